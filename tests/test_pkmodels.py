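"""Kinetic forward models, exact convolution, and per-curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dce2tcm as d
from dce2tcm.pkmodels import _twotcm_curve_fit_space


def brute_force_convolve(cp, t, k, refine=100):
    """Trapezoidal convolution on a refined grid (independent oracle)."""
    tf = np.linspace(t[0], t[-1], (t.size - 1) * refine + 1)
    cpf = np.interp(tf, t, cp)
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        sel = tf <= ti + 1e-12
        out[i] = np.trapezoid(cpf[sel] * np.exp(-k * (ti - tf[sel])), tf[sel])
    return out


class TestExpConvolve:
    def test_zero_input_gives_zero_output(self, times_min):
        out = d.exp_convolve(np.zeros_like(times_min), times_min, 0.7)
        assert np.all(out == 0)

    def test_constant_input_matches_closed_form(self):
        t = np.linspace(0, 4, 241)
        out = d.exp_convolve(np.ones_like(t), t, 0.5)
        # integral of exp(-k(t-tau)) dtau = (1 - e^{-kt})/k
        expected = (1 - np.exp(-0.5 * t)) / 0.5
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-14)
        assert out[np.searchsorted(t, 2.0)] == pytest.approx(1.26424, abs=1e-5)

    def test_k_zero_equals_cumulative_trapezoid(self, times_min, phantom_aif):
        from scipy.integrate import cumulative_trapezoid

        out = d.exp_convolve(phantom_aif.cp_mM, times_min, 0.0)
        np.testing.assert_allclose(out, cumulative_trapezoid(phantom_aif.cp_mM, times_min, initial=0))

    # the trapezoid oracle's own error is O((kh)^2), so fast rates need a
    # finer oracle grid for a meaningful 1e-6 comparison
    @pytest.mark.parametrize("k, refine", [(0.05, 100), (0.5, 100), (2.0, 1000), (9.0, 1000)])
    def test_matches_refined_grid_brute_force(self, times_min, k, refine):
        rng = np.random.default_rng(42)
        cp = rng.uniform(0, 5, times_min.size)
        ours = d.exp_convolve(cp, times_min, k)
        ref = brute_force_convolve(cp, times_min, k, refine=refine)
        scale = np.max(np.abs(ref))
        assert np.max(np.abs(ours - ref)) / scale < 1e-6

    def test_output_starts_at_zero_and_is_finite(self, times_min, phantom_aif):
        out = d.exp_convolve(phantom_aif.cp_mM, times_min, 3.0)
        assert out[0] == 0.0 and np.all(np.isfinite(out))

    def test_negative_rate_rejected(self, times_min):
        with pytest.raises(ValueError):
            d.exp_convolve(np.ones_like(times_min), times_min, -0.1)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            d.exp_convolve(np.ones(3), np.array([0.0, 2.0, 1.0]), 0.5)

    def test_overflow_safe_fallback_matches_recursion(self):
        # rate large enough that exp(k t) would overflow the cumsum route
        t = np.linspace(0, 8, 61)
        cp = np.sin(t) ** 2
        fast = d.exp_convolve(cp, t, 100.0)
        ref = brute_force_convolve(cp, t, 100.0, refine=400)
        assert np.all(np.isfinite(fast))
        np.testing.assert_allclose(fast[1:], ref[1:], rtol=1e-4, atol=1e-8)


class TestForwardModels:
    def test_tofts_zero_ktrans_gives_zero_curve(self, phantom_aif):
        out = d.tofts_forward(d.ToftsParams(0.0, 0.5), phantom_aif)
        assert np.all(out == 0)

    def test_tofts_constant_input_closed_form(self):
        t = np.linspace(0, 4, 2401)
        aif = d.AIF(times_min=t, cp_mM=np.ones_like(t))
        out = d.tofts_forward(d.ToftsParams(0.2, 0.5), aif)
        # Ktrans/kep (1 - e^{-kep t}) at t = 2 min
        assert out[np.searchsorted(t, 2.0)] == pytest.approx(0.25285, abs=1e-5)

    def test_tofts_linear_in_ktrans(self, phantom_aif):
        c1 = d.tofts_forward(d.ToftsParams(0.15, 0.8), phantom_aif)
        c2 = d.tofts_forward(d.ToftsParams(0.30, 0.8), phantom_aif)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_2tcm_eps_zero_reduces_to_tofts(self, phantom_aif):
        p = d.TwoTCMParams.from_fit_space(0.2, 0.7, 0.0, 1.3)
        c2 = d.twotcm_forward(p, phantom_aif)
        c1 = d.tofts_forward(d.ToftsParams(0.2, 0.7), phantom_aif)
        np.testing.assert_allclose(c2, c1, rtol=0, atol=1e-12)

    def test_2tcm_lam_zero_reduces_to_scaled_tofts(self, phantom_aif):
        p = d.TwoTCMParams.from_fit_space(0.2, 0.7, 0.5, 0.0)
        c2 = d.twotcm_forward(p, phantom_aif)
        c1 = d.tofts_forward(d.ToftsParams(0.2 * 1.5, 0.7), phantom_aif)
        np.testing.assert_allclose(c2, c1, rtol=0, atol=1e-12)

    def test_2tcm_constant_input_closed_form(self):
        t = np.linspace(0, 4, 2401)
        aif = d.AIF(times_min=t, cp_mM=np.ones_like(t))
        p = d.TwoTCMParams.from_fit_space(0.2, 0.5, 0.5, 0.0)
        out = d.twotcm_forward(p, aif)
        assert out[np.searchsorted(t, 2.0)] == pytest.approx(0.37927, abs=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        k1=st.floats(0.01, 2.0),
        kep1=st.floats(0.01, 5.0),
        eps=st.floats(0.0, 10.0),
        lam=st.floats(0.0, 5.0),
    )
    def test_two_term_and_factored_forms_agree(self, k1, kep1, eps, lam):
        t = np.arange(60) * 8.3 / 60
        aif = d.synthetic_aif(t)
        p = d.TwoTCMParams.from_fit_space(k1, kep1, eps, lam)
        a = d.twotcm_forward(p, aif, form="two_term")
        b = d.twotcm_forward(p, aif, form="factored")
        assert np.max(np.abs(a - b)) <= 1e-12


class TestCanonicalize:
    def test_swaps_when_second_amplitude_larger(self):
        raw = d.TwoTCMParams(0.05, 0.3, 0.20, 1.1)
        out = d.canonicalize_2tcm(raw)
        assert (out.k1trans, out.kep1, out.k2trans, out.kep2) == (0.20, 1.1, 0.05, 0.3)

    def test_idempotent_on_ordered_input(self):
        p = d.TwoTCMParams(0.25, 1.2, 0.05, 0.2)
        assert d.canonicalize_2tcm(p) == p
        assert d.canonicalize_2tcm(d.canonicalize_2tcm(p)) == p

    def test_equal_amplitudes_tie_broken_by_faster_rate(self):
        out = d.canonicalize_2tcm(d.TwoTCMParams(0.1, 0.3, 0.1, 2.0))
        assert out.kep1 == 2.0 and out.kep2 == 0.3


class TestRmse:
    def test_identical_curves_give_zero(self):
        c = np.linspace(0, 1, 10)
        assert d.rmse(c, c) == 0.0

    def test_alternating_residuals_hand_value(self):
        a = np.array([0.01, -0.01, 0.01, -0.01])
        assert d.rmse(a, np.zeros(4)) == pytest.approx(0.01, rel=1e-12)

    def test_homogeneous_under_scaling(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert d.rmse(3 * a, 3 * b) == pytest.approx(3 * d.rmse(a, b), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            d.rmse(np.zeros(4), np.zeros(5))


class TestFitTofts:
    def test_noiseless_self_inversion(self, phantom_aif):
        c = d.tofts_forward(d.ToftsParams(0.3, 0.8), phantom_aif)
        r = d.fit_tofts(c, phantom_aif)
        assert r.converged
        assert r.params.ktrans == pytest.approx(0.3, rel=1e-4)
        assert r.params.kep == pytest.approx(0.8, rel=1e-4)

    def test_zero_curve_returns_zero_fit(self, phantom_aif):
        r = d.fit_tofts(np.zeros_like(phantom_aif.cp_mM), phantom_aif)
        assert r.params.ktrans == 0.0 and r.rmse == 0.0 and r.converged

    def test_matches_grid_search_oracle(self, times_min, phantom_aif):
        rng = np.random.default_rng(5)
        true = d.ToftsParams(0.42, 1.7)
        c = d.tofts_forward(true, phantom_aif) + rng.normal(0, 0.02, times_min.size)
        kts = np.linspace(0, 1, 200)
        keps = np.linspace(0, 3, 200)
        convs = np.stack([d.exp_convolve(phantom_aif.cp_mM, times_min, k) for k in keps])
        sse = ((kts[:, None, None] * convs[None, :, :] - c) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        r = d.fit_tofts(c, phantom_aif)
        assert abs(r.params.ktrans - kts[i]) <= kts[1] - kts[0]
        assert abs(r.params.kep - keps[j]) <= keps[1] - keps[0]

    def test_noisy_recovery_median_error_small(self, phantom_aif):
        true = d.ToftsParams(0.3, 0.9)
        clean = d.tofts_forward(true, phantom_aif)
        noise_sd = 0.01 * clean.max()
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            r = d.fit_tofts(clean + rng.normal(0, noise_sd, clean.size), phantom_aif)
            errs.append(abs(r.params.ktrans - true.ktrans) / true.ktrans)
        assert np.median(errs) <= 0.10


class TestFit2TCM:
    def test_noiseless_self_inversion_within_one_percent(self, phantom_aif):
        true = d.TwoTCMParams(0.25, 1.2, 0.05, 0.2)
        c = d.twotcm_forward(true, phantom_aif)
        r = d.fit_2tcm(c, phantom_aif)
        assert r.converged
        for name in ("k1trans", "kep1", "k2trans", "kep2"):
            assert getattr(r.params, name) == pytest.approx(getattr(true, name), rel=0.01)

    def test_pure_tofts_curve_recovers_tofts_parameters(self, phantom_aif):
        c = d.tofts_forward(d.ToftsParams(0.3, 0.8), phantom_aif)
        r = d.fit_2tcm(c, phantom_aif)
        # degenerate fit: either the extra amplitude or the rate offset vanishes
        assert r.params.k2trans <= 0.02 * r.params.k1trans + 1e-6 or abs(r.params.lam) <= 1e-3
        total = r.params.k1trans + (r.params.k2trans if abs(r.params.lam) <= 1e-3 else 0.0)
        assert total == pytest.approx(0.3, rel=0.02)
        assert r.params.kep1 == pytest.approx(0.8, rel=0.02)

    def test_zero_curve_returns_zero_fit(self, phantom_aif):
        r = d.fit_2tcm(np.zeros_like(phantom_aif.cp_mM), phantom_aif)
        assert r.params.k1trans == 0.0 and r.rmse == 0.0

    def test_nested_rmse_never_worse_than_tofts(self, phantom_aif, times_min):
        rng = np.random.default_rng(9)
        for _ in range(5):
            c = d.twotcm_forward(
                d.TwoTCMParams(0.25, 1.2, 0.05, 0.2), phantom_aif
            ) + rng.normal(0, 0.01, times_min.size)
            rt = d.fit_tofts(c, phantom_aif)
            r2 = d.fit_2tcm(c, phantom_aif)
            assert r2.rmse <= rt.rmse + 1e-9

    def test_noisy_amplitude_recovery_median_error(self, phantom_aif):
        true = d.TwoTCMParams(0.25, 1.2, 0.05, 0.2)
        clean = d.twotcm_forward(true, phantom_aif)
        noise_sd = 0.01 * clean.max()
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            r = d.fit_2tcm(clean + rng.normal(0, noise_sd, clean.size), phantom_aif, seed=seed)
            errs.append(abs(r.params.k1trans - true.k1trans) / true.k1trans)
        assert np.median(errs) <= 0.10


class TestEstimators:
    def test_batch_fit_exposes_sklearn_style_attributes(self, phantom_aif):
        X = np.stack(
            [
                d.tofts_forward(d.ToftsParams(0.1, 0.4), phantom_aif),
                d.tofts_forward(d.ToftsParams(0.3, 1.0), phantom_aif),
            ]
        )
        m = d.ToftsModel(aif=phantom_aif).fit(X)
        np.testing.assert_allclose(m.ktrans_, [0.1, 0.3], rtol=1e-4)
        np.testing.assert_allclose(m.kep_, [0.4, 1.0], rtol=1e-4)
        np.testing.assert_allclose(m.predict(), X, atol=1e-6)
        assert "aif" in m.get_params()

    def test_two_compartment_estimator_roundtrip(self, phantom_aif):
        p = d.TwoTCMParams(0.25, 1.2, 0.05, 0.2)
        X = d.twotcm_forward(p, phantom_aif)[None, :]
        m = d.TwoCompartmentModel(aif=phantom_aif, seed=1).fit(X)
        assert m.k1trans_[0] == pytest.approx(0.25, rel=0.01)
        assert m.kep2_[0] == pytest.approx(0.2, rel=0.01)
        np.testing.assert_allclose(m.predict()[0], X[0], atol=1e-6)

    def test_estimator_rejects_mismatched_grid(self, phantom_aif):
        with pytest.raises(ValueError):
            d.ToftsModel(aif=phantom_aif).fit(np.zeros((2, 10)))
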