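"""Variant calling: posterior over alternate-allele counts, QUAL and genotypes.

Single-sample calling combines the per-sample genotype likelihoods L(g) with
an AFS prior phi over k in {0, 1, 2}:

    P(k | D, F)  propto  phi_k * L(k)

A site is called a variant when P(ref | D, F) = P(k=0 | D, F) falls below the
variant-calling threshold p (default 0.5), and its quality is

    QUAL = -10 * log10 P(k=0 | D, F)

i.e. the Phred-scaled posterior probability of the non-variant state,
including the prior.  This definition reproduces the published worked
examples exactly: a PL triple of (185, 0, 236) yields QUAL 155 under the
full Wright-Fisher prior at theta = 0.001 and 185 under the flat prior.

Multi-sample (joint) calling convolves the per-sample likelihood polynomials
into P(D | k) for k = 0..2n (see
:func:`mosaicall.likelihood.site_likelihoods_over_k`) and applies a prior of
length 2n + 1.  The site QUAL is shared by all samples; per-sample genotypes
are re-scored against Hardy-Weinberg weights at the posterior-mean allele
frequency f_hat = E[k | D] / 2n.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .afs import AFSPrior
from .likelihood import GenotypeLikelihoods, gl_to_pl, site_likelihoods_over_k
from .samio import SitePileup

__all__ = ["CallerConfig", "CallResult", "SampleCall", "call_single", "call_multi"]

_GT_STRINGS = ("0/0", "0/1", "1/1")


@dataclass(frozen=True)
class CallerConfig:
    """Prior + decision threshold for variant calling."""

    prior: AFSPrior
    variant_threshold: float = 0.5
    multi_sample: bool = False

    def __post_init__(self):
        if not (0.0 < self.variant_threshold <= 1.0):
            raise ValueError("variant_threshold must be in (0, 1]")


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    genotype: str  # "0/0", "0/1" or "1/1"
    gq: int
    pl: tuple[int, int, int]


@dataclass
class CallResult:
    """Posterior summary for one site (single- or multi-sample)."""

    p_ref: float
    called: bool
    qual: float
    posterior_k: np.ndarray
    samples: list[SampleCall] = field(default_factory=list)
    dp: int | None = None
    dp4: tuple[int, int, int, int] | None = None

    @property
    def genotype(self) -> str:
        """Genotype of the first (or only) sample."""
        return self.samples[0].genotype

    @property
    def gq(self) -> int:
        return self.samples[0].gq


def _gq_from_posterior(p_best: float) -> int:
    """Phred-scaled genotype confidence, capped at 99."""
    residual = max(1.0 - p_best, 0.0)
    if residual <= 0.0:
        return 99
    return min(99, int(math.floor(-10.0 * math.log10(residual) + 0.5)))


def _posterior(prior: AFSPrior, lik_k: np.ndarray) -> np.ndarray:
    num = prior.phi * lik_k
    total = num.sum()
    if total <= 0.0:
        raise ValueError("all posterior mass vanished; degenerate likelihoods")
    return num / total


def call_single(
    gl: GenotypeLikelihoods,
    config: CallerConfig,
    pileup: SitePileup | None = None,
    alt_allele: str | None = None,
    sample_id: str = "S1",
) -> CallResult:
    """Call one sample at one site; the prior must have M = 2.

    The genotype is the posterior argmax over k (ties break toward the
    reference-preferring lower k) and GQ is the Phred-scaled probability
    that this genotype is wrong, capped at 99.
    """
    if config.prior.M != 2:
        raise ValueError("call_single requires a prior with M=2")
    result = call_multi([gl], config, sample_ids=[sample_id])
    if pileup is not None:
        result.dp = pileup.depth
        if alt_allele is not None:
            result.dp4 = pileup.dp4(alt_allele)
    return result


def call_multi(
    gls: Sequence[GenotypeLikelihoods],
    config: CallerConfig,
    sample_ids: Sequence[str] | None = None,
    pileups: Sequence[SitePileup] | None = None,
    alt_allele: str | None = None,
) -> CallResult:
    """Joint call across samples; the prior must have M = 2 * len(gls).

    With a single sample this reduces exactly to :func:`call_single`: the
    convolution gives P(D | k) = L(k) and the Hardy-Weinberg re-scoring is
    bypassed in favour of the direct posterior argmax.
    """
    n = len(gls)
    if n < 1:
        raise ValueError("need at least one sample")
    M = 2 * n
    if config.prior.M != M:
        raise ValueError(
            f"prior has M={config.prior.M} but {n} samples require M={M}"
        )
    lik_k = site_likelihoods_over_k(gls)
    post = _posterior(config.prior, lik_k)
    p_ref = float(post[0])
    # Decide on the complement mass P(k > 0 | D, F) so that a threshold of
    # 1.0 emits every site carrying any variant evidence even when p_ref
    # rounds to 1.0 in double precision.
    p_var = float(post[1:].sum())
    called = p_var > 1.0 - config.variant_threshold
    qual = max(0.0, -10.0 * math.log10(max(p_ref, 1e-320)))
    f_hat = float((np.arange(M + 1) * post).sum()) / M

    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    samples: list[SampleCall] = []
    if n == 1:
        g = int(np.argmax(post))  # first max: ties break toward lower k
        samples.append(SampleCall(sample_ids[0], _GT_STRINGS[g],
                                  _gq_from_posterior(float(post[g])), gls[0].pl))
    else:
        hw = np.array([(1 - f_hat) ** 2, 2 * f_hat * (1 - f_hat), f_hat ** 2])
        for sid, gl in zip(sample_ids, gls):
            l10 = np.asarray(gl.log10_l)
            lin = 10.0 ** (l10 - l10.max())
            weighted = lin * hw
            total = weighted.sum()
            if total <= 0.0:
                # degenerate f_hat of exactly 0 or 1 with opposing likelihoods
                weighted = lin
                total = weighted.sum()
            pg = weighted / total
            g = int(np.argmax(pg))
            samples.append(SampleCall(sid, _GT_STRINGS[g],
                                      _gq_from_posterior(float(pg[g])), gl.pl))

    result = CallResult(p_ref=p_ref, called=called, qual=qual,
                        posterior_k=post, samples=samples)
    if pileups:
        result.dp = sum(p.depth for p in pileups)
        if alt_allele is not None:
            d4 = np.sum([p.dp4(alt_allele) for p in pileups], axis=0)
            result.dp4 = tuple(int(x) for x in d4)
    return result
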