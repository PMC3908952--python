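"""SAM text parsing, per-site pileups and Phred-scale utilities.

The parser targets the small, indel-free alignment fragments produced by
:mod:`mosaicall.simulate` as well as general SAM text with M/I/D/S/=/X CIGAR
operations.  A minimal per-site pileup TSV dialect (one row per read
observation) is provided as an alternative caller input so that the genotype
model can be exercised without any SAM plumbing.

Coordinates are 1-based inclusive (SAM/VCF convention); query offsets are
0-based internally.
"""
from __future__ import annotations

import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: SAM flag bits that exclude a read from pileups: unmapped, secondary,
#: QC-fail and duplicate (duplicate detection itself is upstream's job).
EXCLUDE_FLAG_MASK = 0x4 | 0x100 | 0x200 | 0x400

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

PILEUP_TSV_COLUMNS = [
    "chrom", "pos", "ref", "sample", "allele", "bq", "mq", "strand", "tail_dist",
]


class SamParseError(ValueError):
    """Raised for malformed SAM lines; the message names the offending line."""


# ---------------------------------------------------------------------------
# Phred scale
# ---------------------------------------------------------------------------

def phred_to_prob(q: float) -> float:
    """Error probability for a Phred-scaled quality ``q``."""
    return 10.0 ** (-q / 10.0)


def prob_to_phred(p: float) -> float:
    """Phred scale of a probability, floored at 1e-320 to avoid -inf."""
    import math

    return -10.0 * math.log10(max(p, 1e-320))


def phred_to_accuracy(q: float) -> float:
    """Base-call accuracy in percent, ``100 * (1 - 10^(-q/10))``.

    Phred 10 is exactly 90%, the moderate-tier quality floor used by the
    hard filters.  Raises ``ValueError`` for negative qualities.
    """
    if q < 0:
        raise ValueError(f"Phred quality must be >= 0, got {q}")
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """One aligned read (a single SAM alignment line)."""

    name: str
    flag: int
    chrom: str
    pos: int  # 1-based leftmost mapped position
    mapq: int
    cigar: str
    seq: str
    quals: tuple[int, ...]
    md: str | None = None
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_excluded(self) -> bool:
        """True for unmapped/secondary/QC-fail/duplicate reads."""
        return bool(self.flag & EXCLUDE_FLAG_MASK)

    def cigar_ops(self) -> list[tuple[int, str]]:
        ops = [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]
        if "".join(f"{n}{op}" for n, op in ops) != self.cigar:
            raise SamParseError(f"read {self.name!r}: malformed CIGAR {self.cigar!r}")
        return ops

    def query_length(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in "MIS=X")

    def reference_length(self) -> int:
        return sum(n for n, op in self.cigar_ops() if op in "MDN=X")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.reference_length() - 1

    def query_offset_at(self, ref_pos: int) -> int | None:
        """0-based query offset aligned to ``ref_pos``.

        Returns ``None`` when the position falls outside the alignment or on
        a non-aligning operation (deletion/skip), i.e. only M/=/X positions
        yield an observation.
        """
        rpos = self.pos
        qoff = 0
        for n, op in self.cigar_ops():
            if op in "M=X":
                if rpos <= ref_pos < rpos + n:
                    return qoff + (ref_pos - rpos)
                rpos += n
                qoff += n
            elif op in "IS":
                qoff += n
            elif op in "DN":
                if rpos <= ref_pos < rpos + n:
                    return None
                rpos += n
            # H/P consume nothing
        return None


def parse_sam(text: str) -> list[ReadRecord]:
    """Parse SAM text (header optional) into :class:`ReadRecord` objects.

    Reads flagged unmapped/secondary/duplicate/QC-fail are returned with
    ``is_excluded`` set rather than dropped, so callers can mirror the usual
    duplicate-removal preprocessing.  Malformed lines raise
    :class:`SamParseError` naming the line.
    """
    records: list[ReadRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise SamParseError(
                f"line {lineno}: expected >= 11 tab-separated columns, got {len(fields)}"
            )
        try:
            flag = int(fields[1])
            pos = int(fields[3])
            mapq = int(fields[4])
            pnext = int(fields[7])
            tlen = int(fields[8])
        except ValueError as exc:
            raise SamParseError(f"line {lineno}: non-numeric mandatory field ({exc})") from None
        seq = fields[9]
        qual = fields[10]
        quals: tuple[int, ...]
        quals = () if qual == "*" else tuple(ord(c) - 33 for c in qual)
        md = None
        for tag in fields[11:]:
            if tag.startswith("MD:Z:"):
                md = tag[5:]
        rec = ReadRecord(
            name=fields[0], flag=flag, chrom=fields[2], pos=pos, mapq=mapq,
            cigar=fields[5], seq=seq, quals=quals, md=md,
            rnext=fields[6], pnext=pnext, tlen=tlen,
        )
        if seq != "*" and quals and len(seq) != len(quals):
            raise SamParseError(
                f"line {lineno}: SEQ length {len(seq)} != QUAL length {len(quals)}"
            )
        if rec.cigar != "*" and seq != "*":
            try:
                qlen = rec.query_length()
            except SamParseError as exc:
                raise SamParseError(f"line {lineno}: {exc}") from None
            if qlen != len(seq):
                raise SamParseError(
                    f"line {lineno}: CIGAR consumes {qlen} query bases but SEQ has {len(seq)}"
                )
        if md is not None and rec.cigar != "*":
            if md_reference_length(md) != rec.reference_length():
                raise SamParseError(
                    f"line {lineno}: MD tag {md!r} inconsistent with CIGAR {rec.cigar!r}"
                )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# MD tags
# ---------------------------------------------------------------------------

def _md_items(md: str):
    """Yield ('m', n) match runs, ('x', base) mismatches, ('d', bases) deletions."""
    pos = 0
    for m in _MD_RE.finditer(md):
        if m.start() != pos:
            raise SamParseError(f"malformed MD tag {md!r}")
        pos = m.end()
        num, dele, sub = m.groups()
        if num is not None:
            n = int(num)
            if n:
                yield ("m", n)
        elif dele is not None:
            yield ("d", dele[1:].upper())
        else:
            yield ("x", sub.upper())
    if pos != len(md):
        raise SamParseError(f"malformed MD tag {md!r}")


def md_reference_length(md: str) -> int:
    """Number of reference bases the MD tag accounts for."""
    total = 0
    for kind, val in _md_items(md):
        total += val if kind == "m" else len(val)
    return total


def reference_from_alignment(read: ReadRecord) -> str:
    """Reconstruct the aligned reference bases from SEQ + CIGAR + MD."""
    if read.md is None:
        raise ValueError(f"read {read.name!r} has no MD tag")
    items = list(_md_items(read.md))
    idx = 0
    pending = 0  # remaining bases of the current match run

    def next_aligned(qbase: str) -> str:
        nonlocal idx, pending
        while True:
            if pending:
                pending -= 1
                return qbase
            if idx >= len(items):
                raise SamParseError(f"MD tag {read.md!r} exhausted before CIGAR")
            kind, val = items[idx]
            idx += 1
            if kind == "m":
                pending = val
            elif kind == "x":
                return val
            else:
                raise SamParseError(f"MD deletion where CIGAR has alignment in {read.md!r}")

    ref: list[str] = []
    qoff = 0
    for n, op in read.cigar_ops():
        if op in "M=X":
            for _ in range(n):
                ref.append(next_aligned(read.seq[qoff]))
                qoff += 1
        elif op in "IS":
            qoff += n
        elif op == "D":
            if pending or idx >= len(items) or items[idx][0] != "d":
                raise SamParseError(f"MD tag {read.md!r} lacks deletion for CIGAR D op")
            bases = items[idx][1]
            idx += 1
            if len(bases) != n:
                raise SamParseError(f"MD deletion length mismatch in {read.md!r}")
            ref.extend(bases)
        elif op == "N":
            raise SamParseError("cannot reconstruct reference across N skips")
    return "".join(ref)


def md_from_alignment(read: ReadRecord, ref: str) -> str:
    """Derive a canonical MD tag from SEQ + CIGAR and the aligned reference.

    ``ref`` must cover exactly the reference span of the alignment (as
    returned by :func:`reference_from_alignment`).
    """
    out: list[str] = []
    run = 0
    qoff = 0
    roff = 0
    for n, op in read.cigar_ops():
        if op in "M=X":
            for _ in range(n):
                if read.seq[qoff].upper() == ref[roff].upper():
                    run += 1
                else:
                    out.append(str(run))
                    out.append(ref[roff].upper())
                    run = 0
                qoff += 1
                roff += 1
        elif op in "IS":
            qoff += n
        elif op == "D":
            out.append(str(run))
            run = 0
            out.append("^" + ref[roff:roff + n].upper())
            roff += n
    out.append(str(run))
    return "".join(out)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseObservation:
    """One read's base observation at a site (a row of the data D)."""

    allele: str
    base_quality: int
    mapping_quality: int
    strand: str  # '+' or '-'
    dist_from_nearer_read_end: int


@dataclass
class SitePileup:
    """All read observations overlapping one genomic site for one sample."""

    chrom: str
    pos: int
    ref_allele: str
    sample_id: str
    observations: tuple[BaseObservation, ...] = ()

    def __post_init__(self):
        self.observations = tuple(self.observations)

    @property
    def depth(self) -> int:
        return len(self.observations)

    def allele_counts(self) -> Counter:
        return Counter(o.allele for o in self.observations)

    def alt_allele(self) -> str | None:
        """Non-reference allele with the highest base-quality sum.

        Ties break alphabetically; returns ``None`` for an all-reference
        pileup.  Remaining non-reference alleles are treated as errors by the
        genotype model, matching a biallelic output convention.
        """
        qsum: dict[str, int] = {}
        for o in self.observations:
            if o.allele != self.ref_allele:
                qsum[o.allele] = qsum.get(o.allele, 0) + o.base_quality
        if not qsum:
            return None
        return min(qsum, key=lambda a: (-qsum[a], a))

    def dp4(self, alt_allele: str) -> tuple[int, int, int, int]:
        """(ref+, ref-, alt+, alt-) strand counts."""
        rf = rr = af = ar = 0
        for o in self.observations:
            if o.allele == self.ref_allele:
                if o.strand == "+":
                    rf += 1
                else:
                    rr += 1
            elif o.allele == alt_allele:
                if o.strand == "+":
                    af += 1
                else:
                    ar += 1
        return (rf, rr, af, ar)

    def alt_fraction(self, alt_allele: str) -> float:
        if self.depth == 0:
            return 0.0
        n_alt = sum(1 for o in self.observations if o.allele == alt_allele)
        return n_alt / self.depth


def pileup_from_reads(
    reads: Iterable[ReadRecord],
    chrom: str,
    pos: int,
    ref_allele: str,
    sample_id: str = "S1",
) -> SitePileup:
    """Build the per-site pileup from covering, non-excluded reads.

    Only M/=/X-aligned positions contribute; reads whose CIGAR places a
    non-aligning operation at the site are skipped with a logged warning.
    """
    obs: list[BaseObservation] = []
    for read in reads:
        if read.is_excluded or read.chrom != chrom:
            continue
        if not (read.pos <= pos <= read.end):
            continue
        off = read.query_offset_at(pos)
        if off is None:
            log.warning(
                "read %s covers %s:%d with a non-aligning CIGAR op; skipped",
                read.name, chrom, pos,
            )
            continue
        base = read.seq[off].upper()
        if base not in "ACGT":
            log.warning("read %s has ambiguous base %r at %s:%d; skipped",
                        read.name, base, chrom, pos)
            continue
        obs.append(
            BaseObservation(
                allele=base,
                base_quality=read.quals[off] if read.quals else 0,
                mapping_quality=read.mapq,
                strand="-" if read.is_reverse else "+",
                dist_from_nearer_read_end=min(off, len(read.seq) - 1 - off),
            )
        )
    return SitePileup(chrom=chrom, pos=pos, ref_allele=ref_allele.upper(),
                      sample_id=sample_id, observations=tuple(obs))


# ---------------------------------------------------------------------------
# Pileup TSV dialect
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileups: Sequence[SitePileup]) -> str:
    rows = []
    for p in pileups:
        for o in p.observations:
            rows.append((p.chrom, p.pos, p.ref_allele, p.sample_id, o.allele,
                         o.base_quality, o.mapping_quality, o.strand,
                         o.dist_from_nearer_read_end))
    df = pd.DataFrame(rows, columns=PILEUP_TSV_COLUMNS)
    return df.to_csv(sep="\t", index=False)


def read_pileup_tsv(source: str) -> list[SitePileup]:
    """Read the pileup TSV dialect; ``source`` is a path or TSV text."""
    if "\t" in source or "\n" in source:
        handle: io.StringIO | str = io.StringIO(source)
    else:
        handle = source
    df = pd.read_csv(handle, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(PILEUP_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    pileups = []
    for (chrom, pos, ref, sample), grp in df.groupby(
            ["chrom", "pos", "ref", "sample"], sort=False):
        obs = tuple(
            BaseObservation(str(r.allele), int(r.bq), int(r.mq), str(r.strand),
                            int(r.tail_dist))
            for r in grp.itertuples()
        )
        pileups.append(SitePileup(str(chrom), int(pos), str(ref), str(sample), obs))
    return pileups
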