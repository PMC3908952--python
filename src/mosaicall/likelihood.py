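"""Per-sample diploid genotype likelihoods from a site pileup.

The model computes the likelihood of the observed bases given each diploid
genotype g in {0, 1, 2} copies of the alternate allele.  Each read contributes
a two-component mixture

    P(b | g) = (1 - g/2) * P(b | ref) + (g/2) * P(b | alt)

with P(b | a) = 1 - e when the observed base matches allele ``a`` and e
otherwise, where e is the per-base error probability derived from the base
and mapping qualities.  Bases matching neither the reference nor the chosen
alternate contribute the error term to both mixture components, so they shift
all three genotype likelihoods equally.

Treating a mismatch as probability e (rather than e/3 spread over the three
possible miscalls) keeps the heterozygote likelihood at exactly 0.5 per read
and is what calibrates the sensitivity sweep against the published minimum
detectable allele fractions; see docs/methods.md for the discussion.

Two error modes are provided:

* ``independent`` -- every read uses its own qualities unchanged.
* ``correlated`` -- within each observed-allele class, reads are sorted by
  descending base quality and the i-th read (0-based) has its base quality
  discounted geometrically to ``q * eta**i`` before conversion to e.  This
  emulates the diminishing evidential value of stacked identical base calls
  caused by correlated sequencing/alignment error.  ``eta = 1`` reproduces
  the independent mode exactly.

BAQ (base alignment quality from probabilistic realignment) is a no-op here:
the simulated and fixture reads are indel-free, where realignment leaves
qualities unchanged.  Externally BAQ-adjusted base qualities can simply be
supplied in the pileup.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import comb

from .samio import SitePileup

__all__ = [
    "ErrorModelConfig",
    "GenotypeLikelihoods",
    "effective_error",
    "genotype_log_likelihoods",
    "gl_to_pl",
    "site_likelihoods_over_k",
]


@dataclass(frozen=True)
class ErrorModelConfig:
    """Error-model settings shared by the caller and the sensitivity sweep.

    eta is the error-dependency coefficient of the correlated mode: the
    fraction of a read's base quality retained per additional same-allele
    read ranked above it.  It is a calibration parameter; the sensitivity
    module freezes the value calibrated against the published sweep averages.
    """

    mode: str = "correlated"
    eta: float = 0.83
    max_quality_cap: float = 63.0
    max_error_cap: float = 0.75

    def __post_init__(self):
        if self.mode not in ("independent", "correlated"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if self.max_quality_cap <= 0 or self.max_error_cap <= 0:
            raise ValueError("quality/error caps must be positive")


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """log10 likelihoods for 0/1/2 alternate-allele copies, plus Phred PLs."""

    log10_l: tuple[float, float, float]
    pl: tuple[int, int, int]

    @classmethod
    def from_log10(cls, log10_l: Sequence[float]) -> "GenotypeLikelihoods":
        l = tuple(float(x) for x in log10_l)
        return cls(l, gl_to_pl(l))

    @classmethod
    def from_pl(cls, pl: Sequence[int]) -> "GenotypeLikelihoods":
        """Likelihoods implied by a Phred-scaled PL triple (best genotype 0)."""
        l = tuple(-float(p) / 10.0 for p in pl)
        return cls(l, gl_to_pl(l))


def effective_error(base_quality: float, mapping_quality: float,
                    config: ErrorModelConfig = ErrorModelConfig()) -> float:
    """Per-base error probability from base and mapping qualities.

    The smaller of the two qualities governs (a confidently called base on a
    dubiously mapped read is still dubious), capped at ``max_quality_cap``;
    the resulting probability is clamped to ``max_error_cap`` so a single
    terrible base can never carry unbounded weight.
    """
    q = min(base_quality, mapping_quality, config.max_quality_cap)
    q = max(q, 0.0)
    return min(10.0 ** (-q / 10.0), config.max_error_cap)


def gl_to_pl(log10_l: Sequence[float]) -> tuple[int, int, int]:
    """Phred-scale a log10 likelihood triple (min PL is 0).

    Rounds half away from zero and clamps at zero, so the best genotype is
    always PL 0.
    """
    m = max(log10_l)
    pl = []
    for l in log10_l:
        raw = -10.0 * (l - m)
        pl.append(max(0, int(math.floor(raw + 0.5))))
    return tuple(pl)  # type: ignore[return-value]


def _effective_qualities(site: SitePileup, config: ErrorModelConfig) -> list[float]:
    """Base quality per observation after any correlated-mode discounting."""
    if config.mode == "independent" or config.eta == 1.0:
        return [float(o.base_quality) for o in site.observations]
    by_allele: dict[str, list[int]] = {}
    for idx, o in enumerate(site.observations):
        by_allele.setdefault(o.allele, []).append(idx)
    quals = [0.0] * len(site.observations)
    for indices in by_allele.values():
        ranked = sorted(indices, key=lambda i: -site.observations[i].base_quality)
        for rank, i in enumerate(ranked):
            quals[i] = site.observations[i].base_quality * config.eta ** rank
    return quals


def genotype_log_likelihoods(
    site: SitePileup,
    alt_allele: str,
    config: ErrorModelConfig = ErrorModelConfig(),
) -> GenotypeLikelihoods:
    """Likelihood of the pileup under 0/1/2 copies of ``alt_allele``.

    An empty pileup is uninformative: all log10 likelihoods are 0 and the PL
    triple is (0, 0, 0).
    """
    alt_allele = alt_allele.upper()
    if alt_allele == site.ref_allele:
        raise ValueError("alternate allele must differ from the reference allele")
    if site.depth == 0:
        return GenotypeLikelihoods((0.0, 0.0, 0.0), (0, 0, 0))
    quals = _effective_qualities(site, config)
    l = [0.0, 0.0, 0.0]
    for o, q in zip(site.observations, quals):
        e = effective_error(q, o.mapping_quality, config)
        p_ref = 1.0 - e if o.allele == site.ref_allele else e
        p_alt = 1.0 - e if o.allele == alt_allele else e
        l[0] += math.log10(p_ref)
        l[1] += math.log10(0.5 * (p_ref + p_alt))
        l[2] += math.log10(p_alt)
    triple = (l[0], l[1], l[2])
    return GenotypeLikelihoods(triple, gl_to_pl(triple))


def site_likelihoods_over_k(gls: Sequence[GenotypeLikelihoods]) -> np.ndarray:
    """Joint site likelihood P(D | k) for k = 0..2n alternate alleles.

    With n samples and per-sample diploid likelihoods L_i(g),

        P(D | k) = (1 / C(2n, k)) * sum over genotype vectors with sum g_i = k
                   of  prod_i C(2, g_i) * L_i(g_i)

    computed by sequential polynomial convolution over samples rather than
    explicit enumeration.  Each sample's likelihoods are rescaled by their
    maximum first, so the returned vector is on an arbitrary common scale --
    exactly what a posterior computation needs and numerically safe for
    hundreds of samples.
    """
    poly = np.array([1.0])
    weights = np.array([1.0, 2.0, 1.0])
    for gl in gls:
        l10 = np.asarray(gl.log10_l, dtype=float)
        lin = 10.0 ** (l10 - l10.max())
        poly = np.convolve(poly, lin * weights)
    m = poly.size - 1
    return poly / comb(m, np.arange(m + 1))
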