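"""Hard filters: PV4 bias statistics, HWE, repeat exclusion and tier criteria.

After calling, variants are stratified into two hard-filter tiers:

* **Tier 1 (moderate):** base-call accuracy >= 90% (QUAL >= 10), total depth
  >= 4, alternate depth >= 2, strand-bias P >= 1e-4, base-quality-bias
  P >= 1e-100, tail-bias P >= 1e-4, HWE P >= 1e-4, and exclusion of variants
  within or adjacent to repetitive DNA including homopolymers >= 5 bp.
* **Tier 2 (stringent):** >= 3 alternate reads, >= 1 alternate read on each
  strand, strand/base-quality/mapping-quality/tail bias P >= 0.01, and
  exclusion of genes known to accumulate spurious pathogenic calls.

The two tiers are evaluated independently: a record may pass tier 1 and fail
tier 2.  The bias statistics mirror the PV4 convention: a two-sided Fisher
exact test on the strand x allele 2x2 table, and two-sided Welch t-tests
comparing base quality, mapping quality and distance-from-nearer-read-end
between reference- and alternate-supporting reads (Mann-Whitney is available
as an option).  Novelty (database membership) is consumed as a precomputed
boolean; the flagged-gene list is user-supplied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .samio import SitePileup
from .vcfio import VariantRecord

__all__ = [
    "FilterConfig",
    "FilterContext",
    "FilterResult",
    "pv4",
    "hwe_p",
    "homopolymer_adjacent",
    "apply_tier",
    "recurrent_genes",
    "read_bed",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for one filter tier; ``None`` disables a criterion."""

    tier: int
    min_qual: float | None = None
    min_dp: int | None = None
    min_alt: int | None = None
    strand_p: float | None = None
    baseq_p: float | None = None
    mapq_p: float | None = None
    tail_p: float | None = None
    hwe_p: float | None = None
    homopolymer_len: int | None = None
    require_alt_both_strands: bool = False
    use_repeat_mask: bool = False
    flagged_genes: frozenset[str] = frozenset()

    @classmethod
    def tier1(cls, repeat_mask: bool = True) -> "FilterConfig":
        return cls(tier=1, min_qual=10.0, min_dp=4, min_alt=2,
                   strand_p=1e-4, baseq_p=1e-100, tail_p=1e-4, hwe_p=1e-4,
                   homopolymer_len=5, use_repeat_mask=repeat_mask)

    @classmethod
    def tier2(cls, flagged_genes: Iterable[str] = ()) -> "FilterConfig":
        return cls(tier=2, min_alt=3, require_alt_both_strands=True,
                   strand_p=0.01, baseq_p=0.01, mapq_p=0.01, tail_p=0.01,
                   flagged_genes=frozenset(flagged_genes))


@dataclass
class FilterContext:
    """Optional site context consumed by tier-1 criteria.

    ``ref_context``/``site_offset`` give local reference sequence for the
    homopolymer scan; ``repeat_mask`` maps chrom -> IntervalTree of 0-based
    half-open repeat intervals; ``genotype_counts`` are cross-sample
    (n_homref, n_het, n_homalt) counts for the HWE test.
    """

    ref_context: str | None = None
    site_offset: int | None = None
    repeat_mask: Mapping[str, IntervalTree] | None = None
    genotype_counts: tuple[int, int, int] | None = None


@dataclass
class FilterResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _two_sample_p(a: Sequence[float], b: Sequence[float],
                  method: str = "welch") -> float:
    """Two-sided location-difference p; 1.0 for degenerate groups."""
    if len(a) < 2 or len(b) < 2:
        return 1.0
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if method == "welch":
        import warnings

        with warnings.catch_warnings():
            # near-constant groups trigger a precision-loss warning; the
            # degenerate cases are handled explicitly above
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif method == "mannwhitney":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown bias-test method {method!r}")
    return 1.0 if math.isnan(p) else float(p)


def pv4(site: SitePileup, alt_allele: str,
        method: str = "welch") -> tuple[float, float, float, float]:
    """(strand, base-quality, mapping-quality, tail-distance) bias p-values.

    Strand bias is a two-sided Fisher exact test on the (ref, alt) x (+, -)
    table; the other three compare the per-read statistic between reference-
    and alternate-supporting reads.  Any comparison lacking two reads per
    group returns p = 1.
    """
    ref_obs = [o for o in site.observations if o.allele == site.ref_allele]
    alt_obs = [o for o in site.observations if o.allele == alt_allele]
    if not ref_obs or not alt_obs:
        return (1.0, 1.0, 1.0, 1.0)
    table = [
        [sum(o.strand == "+" for o in ref_obs), sum(o.strand == "-" for o in ref_obs)],
        [sum(o.strand == "+" for o in alt_obs), sum(o.strand == "-" for o in alt_obs)],
    ]
    strand = float(stats.fisher_exact(table, alternative="two-sided")[1])
    baseq = _two_sample_p([o.base_quality for o in ref_obs],
                          [o.base_quality for o in alt_obs], method)
    mapq = _two_sample_p([o.mapping_quality for o in ref_obs],
                         [o.mapping_quality for o in alt_obs], method)
    tail = _two_sample_p([o.dist_from_nearer_read_end for o in ref_obs],
                         [o.dist_from_nearer_read_end for o in alt_obs], method)
    return (strand, baseq, mapq, tail)


def hwe_p(genotype_counts: tuple[int, int, int]) -> float:
    """Chi-square (1 df) Hardy-Weinberg equilibrium p-value.

    Counts are (hom-ref, het, hom-alt) across samples; with n <= 1 samples or
    a monomorphic site the test is vacuous and returns 1.
    """
    n00, n01, n11 = genotype_counts
    if any(c < 0 for c in genotype_counts):
        raise ValueError("genotype counts must be non-negative")
    n = n00 + n01 + n11
    if n <= 1:
        return 1.0
    f = (n01 + 2 * n11) / (2 * n)
    if f == 0.0 or f == 1.0:
        return 1.0
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2]) * n
    observed = np.array([n00, n01, n11], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def homopolymer_adjacent(ref_context: str, site_offset: int,
                         min_len: int = 5, adjacency: int = 1) -> bool:
    """True if a homopolymer run >= ``min_len`` overlaps the site +- ``adjacency``.

    ``ref_context`` is local reference sequence, ``site_offset`` the 0-based
    position of the variant within it.
    """
    if not (0 <= site_offset < len(ref_context)):
        raise ValueError(
            f"site_offset {site_offset} outside context of length {len(ref_context)}"
        )
    window_lo = site_offset - adjacency
    window_hi = site_offset + adjacency
    i = 0
    n = len(ref_context)
    while i < n:
        j = i
        while j < n and ref_context[j].upper() == ref_context[i].upper():
            j += 1
        if j - i >= min_len and i <= window_hi and j - 1 >= window_lo:
            return True
        i = j
    return False


# ---------------------------------------------------------------------------
# Tier application
# ---------------------------------------------------------------------------

def _require(record: VariantRecord, name: str):
    value = getattr(record, name)
    if value is None:
        raise ValueError(f"record {record.chrom}:{record.pos} lacks required field {name!r}")
    return value


def apply_tier(record: VariantRecord, config: FilterConfig,
               context: FilterContext | None = None) -> FilterResult:
    """Evaluate one record against one tier; reasons list every failure.

    All criteria are monotone: improving any single statistic (higher QUAL,
    more alternate reads, larger bias p-values) can never turn a pass into a
    fail.
    """
    reasons: list[str] = []

    if config.min_qual is not None and _require(record, "qual") < config.min_qual:
        reasons.append("min_qual")
    if config.min_dp is not None and _require(record, "dp") < config.min_dp:
        reasons.append("min_dp")
    if config.min_alt is not None or config.require_alt_both_strands:
        _require(record, "dp4")
    if config.min_alt is not None and record.alt_depth < config.min_alt:
        reasons.append("min_alt")
    if config.require_alt_both_strands and (
            record.alt_forward < 1 or record.alt_reverse < 1):
        reasons.append("alt_both_strands")

    bias_thresholds = (("strand_p", config.strand_p), ("baseq_p", config.baseq_p),
                       ("mapq_p", config.mapq_p), ("tail_p", config.tail_p))
    if any(t is not None for _, t in bias_thresholds):
        pv = _require(record, "pv4")
        values = dict(zip(("strand_p", "baseq_p", "mapq_p", "tail_p"), pv))
        for name, threshold in bias_thresholds:
            if threshold is not None and values[name] < threshold:
                reasons.append(name)

    if config.hwe_p is not None and context is not None \
            and context.genotype_counts is not None:
        if hwe_p(context.genotype_counts) < config.hwe_p:
            reasons.append("hwe")

    if config.homopolymer_len is not None and context is not None \
            and context.ref_context is not None:
        if context.site_offset is None:
            raise ValueError("homopolymer check needs context.site_offset")
        if homopolymer_adjacent(context.ref_context, context.site_offset,
                                min_len=config.homopolymer_len):
            reasons.append("homopolymer")

    if config.use_repeat_mask and context is not None \
            and context.repeat_mask is not None:
        tree = context.repeat_mask.get(record.chrom)
        if tree is not None and tree.overlaps(record.pos - 1, record.pos):
            reasons.append("repeat_mask")

    if config.flagged_genes and record.gene is not None \
            and record.gene in config.flagged_genes:
        reasons.append("flagged_gene")

    return FilterResult(passed=not reasons, reasons=reasons)


def read_bed(path: str) -> dict[str, IntervalTree]:
    """Load a BED repeat mask into per-chromosome interval trees."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    mask: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        mask[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp.start, grp.end) if e > s)
    return mask


# ---------------------------------------------------------------------------
# Cross-sample recurrence
# ---------------------------------------------------------------------------

def recurrent_genes(
    tables: Mapping[str, pd.DataFrame | Iterable[tuple[str, bool]]],
    min_samples: int,
) -> dict[str, int]:
    """Genes carrying novel variants in at least ``min_samples`` samples.

    ``tables`` maps sample id to that sample's passing variants, either a
    DataFrame with ``gene``/``novel`` columns or an iterable of
    (gene, novel) pairs.  Only novel variants count, each sample at most
    once per gene; the result maps gene -> sample count, ordered by count
    (descending) then gene name.
    """
    per_gene: dict[str, set[str]] = {}
    for sample, table in tables.items():
        if isinstance(table, pd.DataFrame):
            pairs = zip(table["gene"], table["novel"])
        else:
            pairs = iter(table)
        for gene, novel in pairs:
            if novel and isinstance(gene, str) and gene:
                per_gene.setdefault(gene, set()).add(sample)
    hits = {g: len(s) for g, s in per_gene.items() if len(s) >= min_samples}
    return dict(sorted(hits.items(), key=lambda kv: (-kv[1], kv[0])))
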