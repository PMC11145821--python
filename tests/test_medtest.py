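"""Joint-significance testing: max-P/BH and the mixture-null FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdmediation import (
    PropensityFit,
    SimulationConfig,
    alpha_inference,
    compute_weights,
    estimate_null_proportions,
    js_mixture_fdr,
    js_uniform,
    simulate_dataset,
)
from hdmediation._wls import wls_fit

pvec = st.lists(st.floats(0.0, 1.0), min_size=2, max_size=60)


def mixture_fdr_oracle(p_alpha, p_beta, pi00, pi01, pi10):
    """Independent double-loop reimplementation of the plug-in estimator."""
    praw = np.maximum(p_alpha, p_beta)
    q = len(praw)
    fdr = np.zeros(q)
    for k in range(q):
        t = praw[k]
        R = int(np.sum(praw <= t))
        V = q * (pi00 * t**2 + pi01 * t + pi10 * t)
        fdr[k] = min(max(V / max(R, 1), 0.0), 1.0)
    # step-up monotonicity: cumulative min from the largest threshold down
    order = np.argsort(praw)
    vals = fdr[order]
    for i in range(q - 2, -1, -1):
        vals[i] = min(vals[i], vals[i + 1])
    out = np.empty(q)
    out[order] = vals
    return out


class TestJsUniform:
    def test_max_statistic(self):
        p_raw, _, _ = js_uniform([0.01], [0.04])
        assert p_raw[0] == 0.04

    def test_textbook_bh_example(self):
        # raw (0.01, 0.02, 0.03, 0.04) with q=4 adjusts to 0.04 everywhere
        pa = np.array([0.01, 0.02, 0.03, 0.04])
        _, p_bh, sig = js_uniform(pa, pa)
        assert np.allclose(p_bh, 0.04)
        assert sig.all()

    def test_single_test_adjustment_is_identity(self):
        _, p_bh, _ = js_uniform([0.03], [0.02])
        assert p_bh[0] == pytest.approx(0.03)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            js_uniform([1.2], [0.5])
        with pytest.raises(ValueError):
            js_uniform([0.1, 0.2], [0.1])

    def test_n_tests_override_scales_adjustment(self):
        pa = np.array([0.001, 0.2])
        _, p_default, _ = js_uniform(pa, pa)
        _, p_wide, _ = js_uniform(pa, pa, n_tests=100)
        assert p_wide[0] == pytest.approx(min(0.001 * 100 / 1, p_wide[1]))
        assert np.all(p_wide >= p_default - 1e-15)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(pvec)
    def test_matches_statsmodels_bh(self, ps):
        from statsmodels.stats.multitest import multipletests

        pa = np.array(ps)
        p_raw, p_bh, _ = js_uniform(pa, pa)
        _, expected, _, _ = multipletests(p_raw, method="fdr_bh")
        assert np.allclose(p_bh, expected, atol=1e-12)
        assert np.all(p_bh >= p_raw - 1e-15)


class TestNullProportions:
    def test_pure_null(self, rng):
        pa = rng.uniform(size=10_000)
        pb = rng.uniform(size=10_000)
        pi00, pi01, pi10 = estimate_null_proportions(pa, pb)
        assert pi00 == pytest.approx(1.0, abs=0.05)
        assert pi01 < 0.05 and pi10 < 0.05

    def test_alpha_null_beta_active(self, rng):
        pa = rng.uniform(size=5000)
        pb = np.full(5000, 1e-8)
        pi00, pi01, pi10 = estimate_null_proportions(pa, pb)
        assert pi01 == pytest.approx(1.0, abs=0.05)

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            estimate_null_proportions([0.5], [0.5])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(pvec, pvec)
    def test_proportions_valid_on_any_input(self, pa, pb):
        m = min(len(pa), len(pb))
        pi = estimate_null_proportions(np.array(pa[:m]), np.array(pb[:m]))
        assert all(0.0 <= x <= 1.0 for x in pi)
        assert sum(pi) <= 1.0 + 1e-12


class TestMixtureFdr:
    def test_zero_threshold_gives_zero_fdr(self):
        pa = np.array([0.0, 0.3])
        pb = np.array([0.0, 0.4])
        _, fdr, sig = js_mixture_fdr(pa, pb, (1.0, 0.0, 0.0))
        assert fdr[0] == 0.0
        assert sig[0]

    def test_plugin_evaluation(self):
        # q=100, pi=(1,0,0); candidate at t=0.05 with R(t)=10 -> 0.025
        pa = np.concatenate([np.linspace(0.001, 0.045, 9), [0.05],
                             np.linspace(0.3, 0.9, 90)])
        _, fdr, _ = js_mixture_fdr(pa, pa, (1.0, 0.0, 0.0))
        assert fdr[9] == pytest.approx(100 * 0.05**2 / 10, abs=1e-12)

    def test_monotone_in_threshold(self, rng):
        pa, pb = rng.uniform(size=200), rng.uniform(size=200)
        p_raw, fdr, _ = js_mixture_fdr(pa, pb)
        order = np.argsort(p_raw)
        assert np.all(np.diff(fdr[order]) >= -1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(pvec, pvec, st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_matches_independent_oracle(self, pa, pb, f0, f1):
        m = min(len(pa), len(pb))
        pa, pb = np.array(pa[:m]), np.array(pb[:m])
        pi00 = f0
        pi01 = (1 - f0) * f1
        pi10 = max(0.0, (1 - f0) * (1 - f1))
        _, fdr, _ = js_mixture_fdr(pa, pb, (pi00, pi01, pi10))
        oracle = mixture_fdr_oracle(pa, pb, pi00, pi01, pi10)
        assert np.allclose(fdr, oracle, atol=1e-12)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            js_mixture_fdr([0.1], [0.1], (0.8, 0.3, 0.2))

    def test_mixture_no_less_powerful_than_bh_with_small_nulls(self, rng):
        # with estimated null mass < 1 and genuine signal, the mixture
        # method's significant set contains the BH set
        pa = np.concatenate([rng.uniform(0, 1e-4, 10), rng.uniform(size=90)])
        pb = np.concatenate([rng.uniform(0, 1e-4, 10), rng.uniform(size=90)])
        _, _, sig_bh = js_uniform(pa, pb)
        _, _, sig_mix = js_mixture_fdr(pa, pb)
        assert set(np.flatnonzero(sig_bh)) <= set(np.flatnonzero(sig_mix))


class TestAlphaInference:
    def test_ra_consistency_large_n(self, big_dataset):
        a, se, p = alpha_inference(big_dataset, [2], adjustment="ra")
        assert abs(a[0] - 0.5) < 0.03
        assert p[0] < 1e-6

    def test_constant_exposure_rejected(self, small_dataset):
        ds = small_dataset
        bad = type(ds)(X=np.zeros(ds.n) + 1.0, Y=ds.Y, M=ds.M, C=ds.C)
        with pytest.raises(ValueError):
            alpha_inference(bad, [0], adjustment="ra")

    def test_empty_candidate_set_is_empty_result(self, small_dataset):
        a, se, p = alpha_inference(small_dataset, [], adjustment="ra")
        assert a.size == se.size == p.size == 0

    def test_constant_ow_weights_match_unweighted(self, small_dataset):
        ds = small_dataset
        fit = PropensityFit(scores=np.full(ds.n, 0.5), coefficients=np.zeros(9),
                            converged=True, n_iterations=1)
        w = compute_weights(fit, ds.X, "ow")
        a_w, _, _ = alpha_inference(ds, [0, 1], adjustment="ow", ps_fit=fit,
                                    weights=w)
        Z = np.column_stack([np.ones(ds.n), ds.X, ds.C])
        a_u = wls_fit(Z, ds.M[:, [0, 1]]).params[1]
        assert np.allclose(a_w, a_u, atol=1e-10)
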