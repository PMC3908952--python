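"""Deterministic mosaic-read simulator for a single variant site.

Generates 100 bp paired-end reads over one site with a configurable number of
alternate-allele reads: reference reads are identical to the reference
(CIGAR 100M, MD:Z:100) and alternate reads carry a single mismatch in the
middle of the read (MD:Z:50G49).  All reads map in the correct orientation
within insert size, alternate evenly between the forward and reverse strand,
and have mapping quality Phred 60 and base qualities Phred 30 throughout.

Mutant fractions are realized as integer alternate-read counts out of the
total depth, so the simulator is a pure function of (depth, n_alt, spec) --
no randomness anywhere.  Mates are placed one insert away and never cover
the site, so site depth equals emitted read count exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .samio import ReadRecord, SitePileup, pileup_from_reads

__all__ = [
    "SimulationSpec",
    "DEFAULT_SPEC",
    "reference_base",
    "reference_sequence",
    "reference_fasta",
    "simulate_site_reads",
    "simulate_sam",
    "sam_text",
    "simulate_grid",
]

_FLAG_PAIRED_FWD = 0x1 | 0x2 | 0x20 | 0x40  # 99: paired, proper, mate rev, first
_FLAG_PAIRED_REV = 0x1 | 0x2 | 0x10 | 0x80  # 147: paired, proper, reverse, second


@dataclass(frozen=True)
class SimulationSpec:
    """Geometry and qualities of the simulated pileup."""

    read_length: int = 100
    base_quality: int = 30
    mapping_quality: int = 60
    mismatch_offset: int = 50  # 0-based query offset of the variant base
    ref_allele: str = "G"
    alt_allele: str = "A"
    chrom: str = "sim1"
    chrom_length: int = 1200
    site_pos: int = 503  # 1-based
    insert_size: int = 300

    def __post_init__(self):
        if not (0 <= self.mismatch_offset < self.read_length):
            raise ValueError("mismatch_offset must lie within the read")
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele must differ from ref allele")
        if self.site_pos - self.mismatch_offset < 1:
            raise ValueError("read start would fall before position 1")
        if self.site_pos + (self.read_length - self.mismatch_offset) > self.chrom_length:
            raise ValueError("read end would fall beyond the contig")


DEFAULT_SPEC = SimulationSpec()


def reference_base(spec: SimulationSpec, pos: int) -> str:
    """Reference base at 1-based ``pos``: a repeating ACGT pattern with the
    configured reference allele forced at the site (no homopolymers)."""
    if pos == spec.site_pos:
        return spec.ref_allele
    return "ACGT"[(pos - 1) % 4]


def reference_sequence(spec: SimulationSpec, start: int, end: int) -> str:
    """Reference bases for the 1-based inclusive interval [start, end]."""
    return "".join(reference_base(spec, p) for p in range(start, end + 1))


def reference_fasta(spec: SimulationSpec = DEFAULT_SPEC, width: int = 60) -> str:
    seq = reference_sequence(spec, 1, spec.chrom_length)
    lines = [f">{spec.chrom}"]
    lines += [seq[i:i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


def simulate_site_reads(
    depth: int, n_alt: int, spec: SimulationSpec = DEFAULT_SPEC
) -> list[ReadRecord]:
    """``depth`` site-covering reads of which ``n_alt`` carry the alternate.

    Reference reads come first, then alternate reads; within each class the
    strand alternates +/- starting on +, so an odd class places its extra
    read on the forward strand.
    """
    if depth < 0 or not (0 <= n_alt <= depth):
        raise ValueError(f"need 0 <= n_alt <= depth, got depth={depth}, n_alt={n_alt}")
    start = spec.site_pos - spec.mismatch_offset
    length = spec.read_length
    ref_seq = reference_sequence(spec, start, start + length - 1)
    off = spec.mismatch_offset
    alt_seq = ref_seq[:off] + spec.alt_allele + ref_seq[off + 1:]
    ref_md = str(length)
    alt_md = f"{off}{spec.ref_allele}{length - off - 1}"

    reads: list[ReadRecord] = []

    def emit(cls: str, index: int, seq: str, md: str) -> None:
        forward = index % 2 == 0
        reads.append(ReadRecord(
            name=f"sim_{cls}_{index + 1}",
            flag=_FLAG_PAIRED_FWD if forward else _FLAG_PAIRED_REV,
            chrom=spec.chrom,
            pos=start,
            mapq=spec.mapping_quality,
            cigar=f"{length}M",
            seq=seq,
            quals=tuple([spec.base_quality] * length),
            md=md,
            rnext="=",
            pnext=start + spec.insert_size - length if forward
                  else start - (spec.insert_size - length),
            tlen=spec.insert_size if forward else -spec.insert_size,
        ))

    for i in range(depth - n_alt):
        emit("ref", i, ref_seq, ref_md)
    for i in range(n_alt):
        emit("alt", i, alt_seq, alt_md)
    return reads


def sam_text(reads: Iterable[ReadRecord], spec: SimulationSpec = DEFAULT_SPEC) -> str:
    """Serialize reads as SAM text with a minimal header."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{spec.chrom}\tLN:{spec.chrom_length}",
    ]
    for r in reads:
        qual = "".join(chr(q + 33) for q in r.quals) if r.quals else "*"
        fields = [r.name, str(r.flag), r.chrom, str(r.pos), str(r.mapq), r.cigar,
                  r.rnext, str(r.pnext), str(r.tlen), r.seq, qual]
        if r.md is not None:
            fields.append(f"MD:Z:{r.md}")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def simulate_sam(depth: int, n_alt: int, spec: SimulationSpec = DEFAULT_SPEC) -> str:
    return sam_text(simulate_site_reads(depth, n_alt, spec), spec)


def simulate_pileup(
    depth: int, n_alt: int, spec: SimulationSpec = DEFAULT_SPEC,
    sample_id: str = "S1",
) -> SitePileup:
    """Pileup at the variant site for one (depth, n_alt) cell."""
    reads = simulate_site_reads(depth, n_alt, spec)
    return pileup_from_reads(reads, spec.chrom, spec.site_pos, spec.ref_allele,
                             sample_id=sample_id)


def simulate_grid(
    depths: Iterable[int] = range(4, 101), spec: SimulationSpec = DEFAULT_SPEC
) -> dict[tuple[int, int], SitePileup]:
    """Pileups for every depth and alternate count up to 50% mutant fraction.

    Keys are (depth, n_alt) with n_alt = 0..floor(depth/2); deterministic.
    """
    grid: dict[tuple[int, int], SitePileup] = {}
    for d in depths:
        for a in range(d // 2 + 1):
            grid[(d, a)] = simulate_pileup(d, a, spec)
    return grid
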