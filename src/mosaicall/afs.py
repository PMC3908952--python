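"""Allele-frequency-spectrum (AFS) priors and their EM refinement.

The AFS prior F = (phi_0 .. phi_M) gives the prior probability that k of the
M sampled chromosomes carry the alternate allele.  It is the "F" of the
calling posterior P(ref | D, F), and the choice of its *initial* shape is
what this package exists to study: a diffuse initial spectrum keeps weight on
low-count variant states and is therefore more sensitive to mosaic
(postzygotic) mutations present in a minority of reads.

Three models are provided:

* ``full`` -- the neutral Wright-Fisher spectrum, phi_k = theta / k for
  k >= 1 with phi_0 absorbing the remainder; theta is the scaled mutation
  rate (default 0.001).
* ``cond2`` -- the spectrum induced by the allele-frequency density
  2(1 - f) of a derived allele observed on two chromosomes,
  phi_k = 2(M + 1 - k) / ((M + 1)(M + 2)).  At M = 2 this is
  (1/2, 1/3, 1/6).
* ``flat`` -- uniform, phi_k = 1 / (M + 1); the maximally diffuse choice.

An optional EM step re-estimates the spectrum from a collection of sites by
iterating phi_k <- mean over sites of the posterior P(k | D_s, phi), the
standard maximum-likelihood update for a mixture over allele counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .likelihood import GenotypeLikelihoods, site_likelihoods_over_k

__all__ = ["AFSPrior", "make_prior", "em_refine"]

_MODELS = ("full", "cond2", "flat")


@dataclass
class AFSPrior:
    """A prior spectrum phi over alternate-allele counts among M chromosomes."""

    model: str
    M: int
    theta: float
    phi: np.ndarray
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.phi.shape != (self.M + 1,):
            raise ValueError(f"phi must have length M+1={self.M + 1}")
        if (self.phi < 0).any():
            raise ValueError("phi entries must be non-negative")
        if abs(self.phi.sum() - 1.0) > 1e-12:
            raise ValueError(f"phi must sum to 1, got {self.phi.sum()!r}")


def make_prior(model: str, M: int = 2, theta: float = 0.001) -> AFSPrior:
    """Construct an initial AFS prior.

    ``M`` is the number of chromosomes (2 x samples, even, >= 2).  ``theta``
    only shapes the ``full`` model; it must satisfy theta * H_M < 1 where
    H_M is the M-th harmonic number, otherwise phi_0 would be negative.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown AFS model {model!r}; choose from {_MODELS}")
    if M < 2 or M % 2:
        raise ValueError(f"M must be an even integer >= 2, got {M}")
    k = np.arange(M + 1)
    if model == "full":
        if theta <= 0:
            raise ValueError("theta must be positive")
        harmonic = np.sum(1.0 / k[1:])
        phi0 = 1.0 - theta * harmonic
        if phi0 < 0:
            raise ValueError(
                f"theta={theta} too large for the full model at M={M} "
                f"(requires theta < {1.0 / harmonic:.6g})"
            )
        phi = np.concatenate(([phi0], theta / k[1:]))
    elif model == "flat":
        phi = np.full(M + 1, 1.0 / (M + 1))
    else:  # cond2
        phi = 2.0 * (M + 1 - k) / ((M + 1) * (M + 2))
    phi = phi / phi.sum()  # absorb rounding at the 1e-16 level
    return AFSPrior(model=model, M=M, theta=theta, phi=phi)


def _site_arrays(
    gl_by_site: Iterable, M: int
) -> list[np.ndarray]:
    """Normalize heterogeneous per-site inputs to P(D|k) arrays of length M+1.

    Accepts, per site, either a single :class:`GenotypeLikelihoods` (one
    sample, M = 2), a sequence of them (multi-sample joint likelihood via
    convolution), or a ready-made array over k.
    """
    arrays = []
    for item in gl_by_site:
        if isinstance(item, GenotypeLikelihoods):
            arr = site_likelihoods_over_k([item])
        elif isinstance(item, np.ndarray):
            arr = np.asarray(item, dtype=float)
        else:
            arr = site_likelihoods_over_k(list(item))
        if arr.shape != (M + 1,):
            raise ValueError(
                f"site likelihood length {arr.size} does not match M+1={M + 1}"
            )
        arrays.append(arr / arr.max())
    return arrays


def em_refine(
    initial: AFSPrior,
    gl_by_site: Iterable,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> AFSPrior:
    """Refine an AFS prior by EM over a collection of sites.

    Each iteration replaces phi_k with the across-site average of the
    posterior P(k | D_s, phi); the observed-data log-likelihood
    sum_s log sum_k phi_k P(D_s | k) is non-decreasing under this update.
    Iteration stops when max_k |delta phi_k| < ``tol`` or after ``max_iter``
    rounds, in which case the result carries ``converged=False`` and a
    warning is emitted (not an exception).
    """
    sites = _site_arrays(gl_by_site, initial.M)
    if not sites:
        raise ValueError("em_refine requires at least one site")
    lik = np.vstack(sites)  # S x (M+1)
    phi = initial.phi.copy()
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        weighted = lik * phi  # S x (M+1)
        post = weighted / weighted.sum(axis=1, keepdims=True)
        new_phi = post.mean(axis=0)
        delta = np.abs(new_phi - phi).max()
        phi = new_phi
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"AFS EM did not converge within {max_iter} iterations", RuntimeWarning
        )
    phi = np.clip(phi, 0.0, None)
    phi = phi / phi.sum()
    return AFSPrior(model=initial.model, M=initial.M, theta=initial.theta,
                    phi=phi, n_iter=n_iter, converged=converged)


def observed_data_log_likelihood(phi: np.ndarray, gl_by_site: Iterable, M: int) -> float:
    """sum_s log sum_k phi_k P(D_s | k), the quantity EM ascends."""
    sites = _site_arrays(gl_by_site, M)
    return float(sum(np.log((np.asarray(phi) * s).sum()) for s in sites))
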