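import pytest

from mosaicall.samio import BaseObservation, SitePileup

# Printed PL triples of the two informative patient sites: the heterozygous
# high-fraction carrier (15/36 alternate reads) and the low-level mosaic
# carrier (4/36 alternate reads).
PATIENT1_PL = (185, 0, 236)
PATIENT2_PL = (12, 0, 233)


def make_pileup(n_ref, n_alt, bq=30, mq=60, ref="G", alt="A",
                tail=49, other=0, other_allele="T", sample="S1"):
    """Hand-built pileup with alternating strands within each allele class."""
    obs = []
    for cls_n, allele in ((n_ref, ref), (n_alt, alt), (other, other_allele)):
        for i in range(cls_n):
            obs.append(BaseObservation(
                allele=allele,
                base_quality=bq if not isinstance(bq, (list, tuple)) else bq[i % len(bq)],
                mapping_quality=mq,
                strand="+" if i % 2 == 0 else "-",
                dist_from_nearer_read_end=tail,
            ))
    return SitePileup(chrom="sim1", pos=503, ref_allele=ref, sample_id=sample,
                      observations=tuple(obs))


@pytest.fixture
def table2_pileup():
    """36-read pileup emulating the low-level mosaic carrier (4 alt reads)."""
    return make_pileup(32, 4)
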