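"""VCF v4.2 serialization of call results.

Records carry the fields the hard filters consume: QUAL, DP, the DP4 strand
counts, the PV4 bias p-values, plus optional gene and novelty annotations and
per-sample GT/PL/GQ.  Writing is plain text emission under this module's
control (floats at %.6g); reading goes through pysam/htslib.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import pysam

from .caller import SampleCall

__all__ = ["VariantRecord", "write_vcf", "read_vcf"]

_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=DP4,Number=4,Type=Integer,Description="Ref-forward, ref-reverse, alt-forward, alt-reverse read counts">',
    '##INFO=<ID=PV4,Number=4,Type=Float,Description="P-values for strand bias, base quality bias, mapping quality bias and tail-distance bias">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene annotation">',
    '##INFO=<ID=NOVEL,Number=1,Type=Integer,Description="1 if absent from the known-variant databases, else 0">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">',
]


@dataclass
class VariantRecord:
    """One biallelic SNV call with the fields the tier filters need."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    dp: int
    dp4: tuple[int, int, int, int]
    pv4: tuple[float, float, float, float] | None = None
    gene: str | None = None
    novel: bool | None = None
    filter_tags: list[str] = field(default_factory=list)
    samples: list[SampleCall] = field(default_factory=list)

    def validate(self) -> None:
        if self.dp != sum(self.dp4):
            raise ValueError(
                f"{self.chrom}:{self.pos}: DP {self.dp} != sum(DP4) {sum(self.dp4)}"
            )
        if self.qual < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative QUAL")
        if self.pv4 is not None and any(not (0.0 <= p <= 1.0) for p in self.pv4):
            raise ValueError(f"{self.chrom}:{self.pos}: PV4 entries must be in [0,1]")

    @property
    def alt_depth(self) -> int:
        return self.dp4[2] + self.dp4[3]

    @property
    def alt_forward(self) -> int:
        return self.dp4[2]

    @property
    def alt_reverse(self) -> int:
        return self.dp4[3]


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_vcf(records: list[VariantRecord]) -> str:
    """Serialize records as VCF v4.2 text (header-only for an empty list)."""
    for rec in records:
        rec.validate()
    sample_ids: list[str] = []
    for rec in records:
        for s in rec.samples:
            if s.sample_id not in sample_ids:
                sample_ids.append(s.sample_id)
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    filters: list[str] = []
    for rec in records:
        for tag in rec.filter_tags:
            if tag not in filters:
                filters.append(tag)

    lines = ["##fileformat=VCFv4.2", "##source=mosaicall"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [f'##FILTER=<ID={t},Description="Failed {t} criterion">'
              for t in filters]
    lines += _HEADER_LINES
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample_ids:
        header += ["FORMAT"] + sample_ids
    lines.append("\t".join(header))

    for rec in records:
        info = [f"DP={rec.dp}", "DP4=" + ",".join(str(c) for c in rec.dp4)]
        if rec.pv4 is not None:
            info.append("PV4=" + ",".join(_fmt_float(p) for p in rec.pv4))
        if rec.gene is not None:
            info.append(f"GENE={rec.gene}")
        if rec.novel is not None:
            info.append(f"NOVEL={int(rec.novel)}")
        row = [
            rec.chrom, str(rec.pos), ".", rec.ref, rec.alt,
            _fmt_float(rec.qual),
            ";".join(rec.filter_tags) if rec.filter_tags else "PASS",
            ";".join(info),
        ]
        if sample_ids:
            row.append("GT:PL:GQ")
            per_sample = {s.sample_id: s for s in rec.samples}
            for sid in sample_ids:
                s = per_sample.get(sid)
                if s is None:
                    row.append("./.:.:.")
                else:
                    pl = ",".join(str(p) for p in s.pl) if s.pl else "."
                    row.append(f"{s.genotype}:{pl}:{s.gq}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_vcf(text: str) -> list[VariantRecord]:
    """Parse VCF text into :class:`VariantRecord` objects via pysam."""
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        records = []
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                info = rec.info
                if "DP" not in info or "DP4" not in info:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos}: missing required INFO key DP/DP4"
                    )
                pv4 = None
                if "PV4" in info:
                    pv4 = tuple(float(p) for p in info["PV4"])
                novel = None
                if "NOVEL" in info:
                    novel = bool(int(info["NOVEL"]))
                samples = []
                for sid in rec.samples:
                    s = rec.samples[sid]
                    gt = s.get("GT")
                    if gt is None or gt[0] is None:
                        continue
                    sep = "|" if s.phased else "/"
                    pl = s.get("PL")
                    samples.append(SampleCall(
                        sample_id=sid,
                        genotype=sep.join(str(a) for a in gt),
                        gq=int(s["GQ"]) if s.get("GQ") is not None else 0,
                        pl=tuple(int(p) for p in pl) if pl is not None else (),
                    ))
                records.append(VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    dp=int(info["DP"]),
                    dp4=tuple(int(c) for c in info["DP4"]),
                    pv4=pv4,
                    gene=info.get("GENE"),
                    novel=novel,
                    filter_tags=[k for k in rec.filter.keys() if k != "PASS"],
                    samples=samples,
                ))
        return records
    finally:
        os.unlink(path)
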