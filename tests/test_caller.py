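"""Posterior calling: QUAL anchors, convolution, thresholds, joint calls."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from mosaicall.afs import make_prior
from mosaicall.caller import CallerConfig, call_multi, call_single
from mosaicall.likelihood import GenotypeLikelihoods, site_likelihoods_over_k

from conftest import PATIENT1_PL, PATIENT2_PL


def _call_pl(pl, model, theta, threshold=1.0):
    cfg = CallerConfig(make_prior(model, 2, theta), threshold)
    return call_single(GenotypeLikelihoods.from_pl(pl), cfg)


class TestQualAnchors:
    """The printed variant qualities follow from PL + prior alone."""

    @pytest.mark.parametrize("pl,model,theta,expected", [
        (PATIENT1_PL, "full", 0.001, 155),
        (PATIENT1_PL, "flat", 0.001, 185),
        (PATIENT1_PL, "cond2", 0.001, 183),
        (PATIENT1_PL, "full", 0.01, 165),
        (PATIENT1_PL, "full", 0.1, 176),
    ])
    def test_high_fraction_site_integer_quals(self, pl, model, theta, expected):
        assert round(_call_pl(pl, model, theta).qual) == expected

    @pytest.mark.parametrize("pl,model,theta,expected", [
        (PATIENT2_PL, "flat", 0.001, 12.3),
        (PATIENT2_PL, "cond2", 0.001, 10.6),
        (PATIENT2_PL, "full", 0.1, 4.57),
        (PATIENT2_PL, "full", 0.001, 0.0684),
    ])
    def test_low_fraction_site_three_sig_figs(self, pl, model, theta, expected):
        qual = _call_pl(pl, model, theta).qual
        assert float(f"{qual:.3g}") == expected

    def test_low_fraction_site_not_called_by_default(self):
        result = _call_pl(PATIENT2_PL, "full", 0.001, threshold=0.5)
        assert not result.called
        assert result.p_ref > 0.5

    def test_low_fraction_site_called_by_flat(self):
        result = _call_pl(PATIENT2_PL, "flat", 0.001, threshold=0.5)
        assert result.called
        assert result.samples[0].genotype == "0/1"

    def test_low_fraction_site_emitted_at_threshold_one(self):
        result = _call_pl(PATIENT2_PL, "full", 0.001, threshold=1.0)
        assert result.called
        assert result.qual == pytest.approx(0.0684, abs=5e-4)


class TestCallSingle:
    def test_no_data_posterior_equals_prior(self):
        gl = GenotypeLikelihoods.from_pl((0, 0, 0))
        result = call_single(gl, CallerConfig(make_prior("full", 2), 0.5))
        assert result.p_ref == pytest.approx(0.9985)
        assert not result.called

    def test_posterior_sums_to_one(self):
        result = _call_pl((40, 0, 90), "full", 0.001)
        assert result.posterior_k.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tie_breaks_toward_reference(self):
        gl = GenotypeLikelihoods.from_pl((0, 0, 0))
        result = call_single(gl, CallerConfig(make_prior("flat", 2), 0.5))
        assert result.samples[0].genotype == "0/0"

    def test_requires_diploid_prior(self):
        with pytest.raises(ValueError):
            call_single(GenotypeLikelihoods.from_pl((0, 0, 0)),
                        CallerConfig(make_prior("flat", 4), 0.5))

    def test_called_iff_posterior_below_threshold(self):
        for threshold in (0.5, 0.75, 1.0):
            result = _call_pl(PATIENT2_PL, "full", 0.001, threshold)
            assert result.called == (result.p_ref < threshold)

    def test_threshold_monotone(self):
        """Any site called at p=0.5 is called at p=0.75 and p=1.0."""
        for pl in [(12, 0, 233), (30, 0, 60), (3, 0, 9), (0, 5, 40)]:
            called = [
                _call_pl(pl, "full", 0.001, threshold).called
                for threshold in (0.5, 0.75, 1.0)
            ]
            assert called == sorted(called)


def brute_force_over_k(gls):
    """Enumeration oracle for the joint likelihood P(D | k)."""
    n = len(gls)
    lik = [10.0 ** (np.array(gl.log10_l) - max(gl.log10_l)) for gl in gls]
    out = np.zeros(2 * n + 1)
    for genotypes in itertools.product(range(3), repeat=n):
        k = sum(genotypes)
        term = 1.0
        for i, g in enumerate(genotypes):
            term *= comb(2, g) * lik[i][g]
        out[k] += term
    return out / comb(2 * n, np.arange(2 * n + 1))


class TestConvolution:
    @given(st.lists(
        st.tuples(st.floats(-30, 0), st.floats(-30, 0), st.floats(-30, 0)),
        min_size=1, max_size=4))
    @settings(max_examples=80, deadline=None)
    def test_matches_enumeration(self, triples):
        gls = [GenotypeLikelihoods.from_log10(t) for t in triples]
        fast = site_likelihoods_over_k(gls)
        slow = brute_force_over_k(gls)
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_probability_conservation_identity(self):
        """sum_k C(2n,k) P(D|k) equals prod_i sum_g C(2,g) L_i(g)."""
        gls = [GenotypeLikelihoods.from_log10(t) for t in
               [(-1.0, 0.0, -3.0), (-0.2, -0.1, 0.0), (0.0, -2.5, -9.0)]]
        n = len(gls)
        lik_k = site_likelihoods_over_k(gls)
        lhs = (comb(2 * n, np.arange(2 * n + 1)) * lik_k).sum()
        rhs = np.prod([
            sum(comb(2, g) * 10.0 ** (gl.log10_l[g] - max(gl.log10_l))
                for g in range(3))
            for gl in gls])
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_single_sample_joint_call_equals_call_single(self):
        gl = GenotypeLikelihoods.from_pl(PATIENT2_PL)
        cfg = CallerConfig(make_prior("full", 2, 0.001), 0.5)
        single = call_single(gl, cfg)
        joint = call_multi([gl], cfg)
        assert joint.p_ref == single.p_ref
        assert joint.qual == single.qual
        assert joint.samples[0].genotype == single.samples[0].genotype


class TestCallMulti:
    def _gls(self, *pls):
        return [GenotypeLikelihoods.from_pl(pl) for pl in pls]

    def test_prior_length_mismatch_rejected(self):
        gls = self._gls((0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError, match="M="):
            call_multi(gls, CallerConfig(make_prior("full", 2), 0.5))

    def test_high_fraction_carrier_rescues_mosaic_sample(self):
        # strong het + weak mosaic + clean negative: called; the weak
        # sample is genotyped heterozygous, one shared site QUAL
        gls = self._gls((185, 0, 236), (12, 0, 233), (0, 80, 500))
        cfg = CallerConfig(make_prior("full", 6, 0.001), 0.5, multi_sample=True)
        result = call_multi(gls, cfg)
        assert result.called
        assert result.samples[0].genotype == "0/1"
        assert result.samples[1].genotype == "0/1"
        assert result.samples[2].genotype == "0/0"

    def test_two_weak_mosaics_and_a_negative_are_not_called(self):
        gls = self._gls((12, 0, 233), (12, 0, 233), (0, 80, 500))
        cfg = CallerConfig(make_prior("full", 6, 0.001), 0.5, multi_sample=True)
        result = call_multi(gls, cfg)
        assert not result.called
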