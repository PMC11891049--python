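"""Segmented least-squares fitters and the full-NLLS oracle."""
import numpy as np
import pytest

from conftest import make_decay
from ivimrad import (FitOptions, IVIMParams, VoxelDecay, fit_full_nlls_oracle,
                     fit_monoexp_loglinear, fit_roi, fit_segmented_lsq,
                     ivim_signal)
from ivimrad.schemes import BValueScheme, site_bvalue_scheme


class TestMonoexpLoglinear:
    def test_exact_monoexponential(self):
        scheme = site_bvalue_scheme("C")
        decay = VoxelDecay(np.exp(-0.001 * scheme.b_values), scheme)
        dt, frac = fit_monoexp_loglinear(decay, 200.0)
        assert dt == pytest.approx(0.001, rel=1e-12)
        assert frac == pytest.approx(1.0, rel=1e-12)

    def test_biexponential_bias_is_small(self):
        s, scheme = make_decay(0.1, 0.01, 0.001)
        dt, frac = fit_monoexp_loglinear(VoxelDecay(s, scheme), 200.0)
        assert dt == pytest.approx(0.001, rel=0.03)
        assert frac < 1.0

    def test_one_pass_bias_at_weak_separation(self):
        # with D_p only ~6x D_t the perfusion signal has not decayed by
        # b=200, and the single-pass high-b fit overestimates D_t badly;
        # this is what the segmented fitters' refinement loop removes
        s, scheme = make_decay(0.2, 0.005, 0.0008, site="A", variant=1)
        dt, _ = fit_monoexp_loglinear(VoxelDecay(s, scheme), 200.0)
        assert (dt - 0.0008) / 0.0008 > 0.10
        r = fit_segmented_lsq(VoxelDecay(s, scheme), "seg_a")
        assert abs(r.params.D_t - 0.0008) / 0.0008 < 0.01

    def test_too_few_high_b_points(self):
        scheme = BValueScheme("C", 1, [0, 50, 100, 800])
        decay = VoxelDecay(np.exp(-0.001 * scheme.b_values), scheme)
        with pytest.raises(ValueError, match="at least 2"):
            fit_monoexp_loglinear(decay, 200.0)


class TestSegmented:
    @pytest.mark.parametrize("variant", ["seg_a", "seg_b"])
    def test_noiseless_recovery(self, variant):
        s, scheme = make_decay(0.10, 0.01, 0.001)
        r = fit_segmented_lsq(VoxelDecay(s, scheme), variant)
        assert r.params.D_t == pytest.approx(0.001, rel=0.03)
        assert r.params.f_p == pytest.approx(0.10, rel=0.10)
        assert r.params.D_p == pytest.approx(0.01, rel=0.15)
        assert r.converged

    def test_monoexponential_degenerate_limit(self):
        scheme = site_bvalue_scheme("C")
        decay = VoxelDecay(np.exp(-0.001 * scheme.b_values), scheme)
        opt = FitOptions()
        r = fit_segmented_lsq(decay, "seg_a", opt)
        assert r.params.f_p <= 1e-6
        assert r.params.D_t == pytest.approx(0.001, rel=1e-10)
        assert r.params.D_p == opt.dp_init  # unidentifiable: initialization
        assert r.converged

    def test_variants_share_step_one(self):
        s, scheme = make_decay(0.15, 0.02, 0.0012, site="A", variant=2)
        ra = fit_segmented_lsq(VoxelDecay(s, scheme), "seg_a")
        rb = fit_segmented_lsq(VoxelDecay(s, scheme), "seg_b")
        assert ra.params.D_t == rb.params.D_t  # identical high-b stage
        assert rb.params.D_p == pytest.approx(ra.params.D_p, rel=0.05)

    def test_unknown_variant(self):
        s, scheme = make_decay(0.1, 0.01, 0.001)
        with pytest.raises(ValueError, match="variant"):
            fit_segmented_lsq(VoxelDecay(s, scheme), "seg_c")

    def test_site_b_falls_inside_threshold_rule(self):
        # Site B has 3 b-values >= 200, so the segmented fit is defined
        s, scheme = make_decay(0.1, 0.01, 0.001, site="B")
        r = fit_segmented_lsq(VoxelDecay(s, scheme), "seg_a")
        assert r.params.D_t == pytest.approx(0.001, rel=0.03)


class TestOracle:
    def test_exact_recovery_with_amplitude(self):
        p = IVIMParams(0.15, 0.02, 0.0009, 100.0)
        scheme = site_bvalue_scheme("A", 2)
        r = fit_full_nlls_oracle(VoxelDecay(ivim_signal(p, scheme.b_values), scheme))
        for name in ("f_p", "D_p", "D_t", "S0"):
            assert getattr(r.params, name) == pytest.approx(
                getattr(p, name), rel=0.005), name
        assert r.residual_norm <= 1e-18
        assert r.converged

    def test_deterministic(self):
        s, scheme = make_decay(0.1, 0.01, 0.001)
        s = np.abs(s + np.random.default_rng(0).normal(0, 0.02, s.shape))
        r1 = fit_full_nlls_oracle(VoxelDecay(s, scheme))
        r2 = fit_full_nlls_oracle(VoxelDecay(s, scheme))
        assert r1.params == r2.params


class TestFitRoi:
    def test_matches_single_voxel_calls_bit_exactly(self):
        scheme = site_bvalue_scheme("C")
        truths = [(0.05, 0.008, 0.0009), (0.1, 0.01, 0.001), (0.2, 0.03, 0.0015)]
        S = np.stack([ivim_signal(IVIMParams(*t), scheme.b_values) for t in truths])
        for method in ("seg_a", "seg_b", "bayes"):
            pmap = fit_roi(S, scheme, method)
            assert len(pmap) == 3
            for v in range(3):
                single = fit_roi(S[v:v + 1], scheme, method).results[0]
                assert pmap.results[v].params == single.params

    def test_order_independent(self, rng):
        scheme = site_bvalue_scheme("B")
        clean = ivim_signal(IVIMParams(0.1, 0.01, 0.001), scheme.b_values)
        S = np.abs(clean + rng.normal(0, 0.02, (8, len(scheme))))
        perm = rng.permutation(8)
        a = fit_roi(S, scheme, "seg_a").values("D_t")
        b = fit_roi(S[perm], scheme, "seg_a").values("D_t")
        np.testing.assert_array_equal(a, b[np.argsort(perm)])

    def test_oracle_map_recovers_truth_map(self):
        scheme = site_bvalue_scheme("C")
        truths = [IVIMParams(0.08, 0.012, 0.0011), IVIMParams(0.12, 0.02, 0.0008),
                  IVIMParams(0.18, 0.04, 0.0014)]
        S = np.stack([ivim_signal(p, scheme.b_values) for p in truths])
        pmap = fit_roi(S, scheme, "oracle")
        for r, p in zip(pmap.results, truths):
            assert r.params.D_t == pytest.approx(p.D_t, rel=0.005)
            assert r.params.f_p == pytest.approx(p.f_p, rel=0.005)
            assert r.params.D_p == pytest.approx(p.D_p, rel=0.005)

    def test_bad_inputs(self):
        scheme = site_bvalue_scheme("B")
        with pytest.raises(ValueError, match="strictly positive"):
            fit_roi(np.zeros((3, len(scheme))), scheme, "seg_a")
        with pytest.raises(ValueError, match="method_tag"):
            fit_roi(np.ones((3, len(scheme))), scheme, "nonsense")


def test_noiseless_bias_bounds_on_truth_grid():
    """Spot-check the segmented noiseless bias bounds away from acceptance."""
    scheme = site_bvalue_scheme("A", 1)
    for fp, dp, dt in [(0.2, 0.005, 0.0008), (0.05, 0.05, 0.0015)]:
        s = ivim_signal(IVIMParams(fp, dp, dt), scheme.b_values)
        r = fit_segmented_lsq(VoxelDecay(s, scheme), "seg_a")
        assert r.params.D_t == pytest.approx(dt, rel=0.03)
        assert r.params.f_p == pytest.approx(fp, rel=0.10)
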