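# mosaicall

Bayesian single- and multi-sample SNP calling tuned for **low-level mosaic
(postzygotic) mutations**, with configurable allele-frequency-spectrum (AFS)
priors, a deterministic mosaic-read simulator, two-tier hard filtering, and a
minimum-detectable-VAF sensitivity evaluation.

## The problem

A mutation that arises after fertilization is present in only a fraction of
cells, so at a heterozygous site the mutant allele may account for far less
than the expected ~50% of sequencing reads. Standard diploid callers use a
neutral Wright–Fisher allele-frequency-spectrum prior that puts almost all
mass on the homozygous-reference state (at scaled mutation rate
θ = 0.001, the prior is (0.9985, 0.001, 0.0005) for 0/1/2 alternate alleles
on two chromosomes), and this prior can override clear read-level evidence
for a low-fraction variant. `mosaicall` implements the calling model with
the prior exposed as a first-class, configurable object so that the
sensitivity cost of each choice can be measured.

## The model

Per sample and site, each read contributes a mixture likelihood over
genotypes g ∈ {0, 1, 2} alternate-allele copies:

    P(b | g) = (1 − g/2) · P(b | ref) + (g/2) · P(b | alt),
    P(b | a) = 1 − e  if b = a,  else  e,
    e = 10^(−min(BQ, MQ, 63)/10)   (clamped to ≤ 0.75)

with an optional correlated-error mode that geometrically discounts the base
qualities of stacked same-allele reads (dependency coefficient η). The site
posterior combines the genotype likelihoods with an AFS prior
F = (φ₀ … φ_M) over the number k of alternate alleles among M chromosomes:

    P(k | D, F) ∝ φ_k · P(D | k),    QUAL = −10·log₁₀ P(k=0 | D, F)

and a variant is called when P(ref | D, F) = P(k=0 | D, F) < p (default 0.5).
Priors: **full** (φ_k = θ/k), **cond2** (φ_k = 2(M+1−k)/((M+1)(M+2)), i.e.
(1/2, 1/3, 1/6) at M = 2), **flat** (uniform). An EM step can refine the
spectrum across sites. Multi-sample calling convolves per-sample likelihood
polynomials into P(D | k) for k = 0..2n and shares one site QUAL across
samples.

## Worked example

Simulate the low-fraction patient-like pileup — 36 reads of which 4 carry
the alternate allele (11.1%), all base qualities Phred 30, mapping qualities
Phred 60, balanced strands — and call it with the default and the flat
prior:

```
$ mosaicall sim --depth 36 --alt-reads 4 --out mosaic.sam
$ mosaicall call --prior full --sam mosaic.sam --site sim1:503:G
#CHROM  POS  ID  REF  ALT  QUAL  FILTER  INFO
$ mosaicall call --prior flat --sam mosaic.sam --site sim1:503:G
#CHROM  POS  ID  REF  ALT  QUAL     FILTER  INFO                             FORMAT    S1
sim1    503  .   G    A    10.1319  PASS    DP=36;DP4=16,16,2,2;PV4=1,1,1,1  GT:PL:GQ  0/1:10,0,659:10
```

The default full prior emits nothing — the site is *not identified* — while
the flat prior calls it heterozygous with QUAL 10.1 (posterior probability
of a non-variant site ≈ 9.7%), just above the tier-1 quality floor of
Phred 10 (90% base-call accuracy). The sensitivity sweep quantifies this
across depths 4–100:

```
$ mosaicall eval --configs default,flat,cond2 --depths 4:100 --summary summary.tsv --out sweep.tsv
$ cut -f1-4 summary.tsv
config   mean_pct            min_pct             max_pct
default  15.48246512848278   11.34020618556701   50.0
flat     11.906064380528738  10.1010101010101    25.0
cond2    11.97128956703955   10.204081632653061  25.0
```

The flat initial AFS detects the variant at a mean minimum mutant-allele
fraction of 11.9% (worst case 25%, at depth 4) versus 15.5% (worst case
50%) for the default configuration — the flat prior needs one fewer
alternate read at almost every depth.

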