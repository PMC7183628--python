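"""Granger-causality estimation: VAR fitting, time- and frequency-domain GC."""

import numpy as np
import pytest

from somnonet.bands import DEFAULT_BANDS
from somnonet.errors import InvalidParameterError
from somnonet.mvgc import (
    MVARModel,
    MvgcSettings,
    autocov_to_var,
    check_integration,
    connectivity_per_subject,
    fit_mvar,
    gc_spectral_from_model,
    gc_time_from_model,
    gc_time_matrix,
    integrate_band,
    mvar_spectrum,
    select_model_order,
    var_to_autocov,
)
from somnonet.synth import _simulate_var

from conftest import FS, make_epochset

# the canonical bivariate benchmark: x_t = .5 x_{t-1} + .4 y_{t-1} + e_x,
# y_t = .7 y_{t-1} + e_y with unit independent noises
BIV = np.zeros((1, 2, 2))
BIV[0] = [[0.5, 0.4], [0.0, 0.7]]


def _scalar_levinson(r, order):
    """Independent univariate Levinson-Durbin: prediction error at `order`."""
    a = np.zeros(order)
    e = r[0]
    for m in range(order):
        acc = r[m + 1] - np.dot(a[:m], r[m:0:-1][:m])
        k = acc / e
        a_new = a.copy()
        a_new[m] = k
        a_new[:m] = a[:m] - k * a[:m][::-1]
        a = a_new
        e *= 1 - k * k
    return e


def _population_f_yx():
    """Population F(y->x) for BIV from analytic autocovariances.

    Gamma_0 solves the 2x2 Lyapunov equation written as a linear system;
    the reduced univariate model for x comes from scalar Levinson-Durbin.
    """
    A = BIV[0]
    G0 = np.linalg.solve(np.eye(4) - np.kron(A, A), np.eye(2).reshape(-1)).reshape(2, 2)
    gx = [G0[0, 0]]
    G = G0
    for _ in range(120):
        G = A @ G
        gx.append(G[0, 0])
    e_red = _scalar_levinson(np.array(gx), 100)
    return np.log(e_red / 1.0)


class TestVarEstimation:
    def test_whittle_matches_block_toeplitz_solve(self):
        rng = np.random.default_rng(2)
        n, p, q = 3, 2, 12
        A = rng.normal(0, 0.25, (p, n, n))
        L = rng.normal(0, 1, (n, n))
        sig = L @ L.T + n * np.eye(n)
        G = var_to_autocov(A, sig, q)
        Aw, Sw = autocov_to_var(G)
        # independent oracle: assemble and solve the block-Toeplitz
        # Yule-Walker system directly
        M = np.zeros((n * q, n * q))
        for r in range(q):
            for c in range(q):
                d = c - r
                M[r * n:(r + 1) * n, c * n:(c + 1) * n] = G[d] if d >= 0 else G[-d].T
        rhs = np.hstack([G[j] for j in range(1, q + 1)])
        Ad = np.linalg.solve(M.T, rhs.T).T.reshape(n, q, n).transpose(1, 0, 2)
        assert np.allclose(Aw, Ad, atol=1e-10)
        assert np.allclose(Aw[:p], A, atol=1e-10)  # true model recovered
        assert np.allclose(Sw, sig, atol=1e-9)

    def test_fit_recovers_known_var_coefficients(self, var3_segments):
        model, segs = var3_segments
        fit = fit_mvar(segs, 3)
        assert np.abs(fit.coeffs - model.coeffs).max() <= 0.05
        assert fit.spectral_radius < 1

    def test_noiseless_recursion_recovered_exactly(self):
        # solutions of the deterministic recursion form a linear space, so
        # combinations of trajectories with exactly zero temporal mean are
        # themselves solutions (they exist for order >= 2, where the initial
        # state has more dimensions than the mean constraint); fitting them
        # is an exact linear system and recovers A to machine precision
        A = np.array([[[0.5, 0.2, 0.0], [0.1, 0.4, 0.1], [0.0, 0.3, 0.2]],
                      [[-0.2, 0.0, 0.1], [0.0, 0.15, 0.0], [0.1, 0.0, -0.25]]])
        rng = np.random.default_rng(3)
        segs = []
        for _ in range(6):
            basis = []
            for _ in range(7):
                x = np.zeros((14, 3))
                x[0] = rng.standard_normal(3)
                x[1] = rng.standard_normal(3)
                for t in range(2, 14):
                    x[t] = A[0] @ x[t - 1] + A[1] @ x[t - 2]
                basis.append(x)
            means = np.stack([b.mean(axis=0) for b in basis], axis=1)  # 3 x 7
            c = np.linalg.svd(means)[2][-1]  # null vector: zero-mean combo
            y = sum(cj * b for cj, b in zip(c, basis))
            assert np.abs(y.mean(axis=0)).max() < 1e-12
            assert np.linalg.norm(y) > 0.1
            segs.append(y.T)
        fit = fit_mvar(np.stack(segs), 2)
        assert np.allclose(fit.coeffs, A, atol=1e-10)
        assert np.abs(fit.resid_cov).max() < 1e-24

    def test_independent_channels_have_small_cross_terms(self):
        rng = np.random.default_rng(4)
        segs = rng.standard_normal((12, 4, 1000))
        fit = fit_mvar(segs, 2)
        mask = ~np.eye(4, dtype=bool)
        cross = fit.coeffs[:, mask]
        # OLS sampling theory: se of a coefficient on unit-variance white
        # noise is ~ 1/sqrt(N)
        se = 1.0 / np.sqrt(fit.n_obs_effective)
        assert np.mean(np.abs(cross) <= 3 * se) >= 0.95


class TestOrderSelection:
    def test_bic_recovers_true_order(self, var3_segments):
        _, segs = var3_segments
        assert select_model_order(segs, p_max=8, criterion="BIC") == 3

    def test_white_noise_selects_order_one_with_tiny_coefficients(self):
        rng = np.random.default_rng(5)
        segs = rng.standard_normal((12, 3, 800))
        p = select_model_order(segs, p_max=6, criterion="BIC")
        assert p == 1
        fit = fit_mvar(segs, p)
        assert np.linalg.norm(fit.coeffs) < 0.1

    def test_determinism(self, var3_segments):
        _, segs = var3_segments
        assert (select_model_order(segs, 6, "AIC")
                == select_model_order(segs, 6, "AIC"))

    def test_bad_criterion_rejected(self, var3_segments):
        _, segs = var3_segments
        with pytest.raises(InvalidParameterError):
            select_model_order(segs, 4, "HQC")


@pytest.fixture(scope="module")
def biv_long():
    model = MVARModel(order=1, coeffs=BIV, resid_cov=np.eye(2))
    x = _simulate_var(model, 100_000, np.random.default_rng(7))
    return x[None, :, :]


class TestTimeDomainGC:

    def test_matches_population_oracle(self, biv_long):
        F_true = _population_f_yx()
        fit = fit_mvar(biv_long, 1)
        F = gc_time_from_model(fit).values
        assert abs(F[1, 0] - F_true) <= 0.02   # y -> x
        assert F[0, 1] <= 0.005                # null direction

    def test_independent_white_noise_is_null(self):
        rng = np.random.default_rng(8)
        segs = rng.standard_normal((1, 3, 100_000))
        F = gc_time_matrix(make_epochset(segs), p=1).values
        assert F.max() <= 0.01

    def test_diagonal_is_zero_and_values_nonnegative(self, var3_segments):
        _, segs = var3_segments
        cm = gc_time_matrix(make_epochset(segs), p=3)
        assert np.all(np.diag(cm.values) == 0)
        assert np.all(cm.values >= 0)
        assert cm.max_clamp <= 1e-10

    def test_bivariate_mode_sees_indirect_influence(self):
        # chain 2 -> 1 -> 0: conditioning on channel 1 blocks the indirect
        # route, the pairwise-marginal (bivariate) analysis does not
        A = np.zeros((1, 3, 3))
        A[0] = [[0.5, 0.4, 0.0], [0.0, 0.5, 0.4], [0.0, 0.0, 0.6]]
        model = MVARModel(order=1, coeffs=A, resid_cov=np.eye(3))
        cond = gc_time_from_model(model, mode="conditional").values
        biv = gc_time_from_model(model, mode="bivariate").values
        assert cond[2, 0] <= 1e-8          # blocked by conditioning
        assert biv[2, 0] > 0.01            # visible marginally
        assert biv[2, 1] > 0.01 and cond[2, 1] > 0.01
        # spectral bivariate mode agrees with its own time-domain integral
        sc = gc_spectral_from_model(model, FS, 256, mode="bivariate")
        full = integrate_band(sc, (0, FS / 2))
        off = ~np.eye(3, dtype=bool)
        mask = off & (biv > 0.01)
        assert np.allclose(full.values[mask], biv[mask], rtol=1e-6)

    def test_amplitude_scale_invariance(self, var3_segments):
        _, segs = var3_segments
        a = gc_time_matrix(make_epochset(segs), p=3).values
        b = gc_time_matrix(make_epochset(segs * 37.5), p=3).values
        assert np.abs(a - b).max() <= 1e-8


class TestSpectrum:
    def test_order_zero_model_has_flat_spectrum(self):
        sig = np.array([[2.0, 0.3], [0.3, 1.0]])
        m = MVARModel(order=0, coeffs=np.zeros((0, 2, 2)), resid_cov=sig)
        _, S = mvar_spectrum(m, np.linspace(0, 100, 64), 200.0)
        assert np.allclose(S, sig)

    def test_univariate_ar1_closed_form_peak(self):
        m = MVARModel(order=1, coeffs=np.full((1, 1, 1), 0.9), resid_cov=np.eye(1))
        freqs = np.linspace(0, 100, 512)
        _, S = mvar_spectrum(m, freqs, 200.0)
        assert np.argmax(S[:, 0, 0].real) == 0
        assert S[0, 0, 0].real == pytest.approx(1.0 / abs(1 - 0.9) ** 2)

    def test_parseval_spectrum_integrates_to_variance(self, var3_segments):
        # 2/fs * integral of S over [0, Nyquist] equals the process variance,
        # checked against a long independent simulation
        model, _ = var3_segments
        freqs = np.linspace(0, FS / 2, 2048)
        _, S = mvar_spectrum(model, freqs, FS)
        var_spec = 2.0 / FS * np.trapezoid(S.real, freqs, axis=0)
        x = _simulate_var(model, 400_000, np.random.default_rng(11))
        var_sim = np.var(x, axis=1)
        assert np.allclose(np.diag(var_spec), var_sim, rtol=0.01)

    def test_hermitian_psd(self, var3_segments):
        model, _ = var3_segments
        _, S = mvar_spectrum(model, np.linspace(0, FS / 2, 128), FS)
        assert np.allclose(S, S.conj().transpose(0, 2, 1))
        eig = np.linalg.eigvalsh(S)
        assert eig.min() > -1e-10


class TestSpectralGC:
    def test_bivariate_closed_form_pointwise(self):
        m = MVARModel(order=1, coeffs=BIV, resid_cov=np.eye(2))
        sc = gc_spectral_from_model(m, FS, 256)
        z = np.exp(-2j * np.pi * sc.freqs / FS)
        hxx = 1 / (1 - 0.5 * z)
        hyy = 1 / (1 - 0.7 * z)
        hxy = 0.4 * z * hxx * hyy
        sxx = np.abs(hxx) ** 2 + np.abs(hxy) ** 2
        f_closed = np.log(sxx / (sxx - np.abs(hxy) ** 2))
        assert np.allclose(sc.values[:, 1, 0], f_closed, atol=1e-12)
        assert np.all(sc.values[:, 0, 1] == 0)

    def test_estimated_bivariate_low_frequency_dominant(self):
        model = MVARModel(order=1, coeffs=BIV, resid_cov=np.eye(2))
        segs = _simulate_var(model, 100_000, np.random.default_rng(13))[None]
        fit = fit_mvar(segs, 1)
        sc = gc_spectral_from_model(fit, FS, 256)
        f_yx = sc.values[:, 1, 0]
        assert f_yx[: 64].mean() > f_yx[-64:].mean()  # concentrated at low freq
        assert sc.values[:, 0, 1].max() <= 0.01

    def test_geweke_identity_on_fitted_model(self, var3_segments):
        _, segs = var3_segments
        fit = fit_mvar(segs, 3)
        tm = gc_time_from_model(fit)
        sc = gc_spectral_from_model(fit, FS, 1024)
        rep = check_integration(sc, tm, rel_tol=0.01)
        assert rep.passed, f"max rel diff {rep.max_rel_diff}"


class TestBandIntegration:
    def test_constant_spectrum_band_mean_is_constant(self):
        freqs = np.linspace(0, 100, 512)
        vals = np.full((512, 2, 2), 0.37)
        from somnonet.mvgc import SpectralConnectivity

        sc = SpectralConnectivity(freqs=freqs, values=vals)
        for band in ((0.25, 3), (8, 12), (16, 32)):
            cm = integrate_band(sc, band)
            off = cm.values[~np.eye(2, dtype=bool)]
            assert np.allclose(off, 0.37)

    def test_band_additivity_recovers_full_integral(self, var3_segments):
        _, segs = var3_segments
        fit = fit_mvar(segs, 3)
        sc = gc_spectral_from_model(fit, FS, 512)
        full = integrate_band(sc, (0, FS / 2)).values * (FS / 2)
        pieces = list(DEFAULT_BANDS.values()) + [(0.0, 0.25), (32.0, FS / 2)]
        total = sum(integrate_band(sc, (lo, hi)).values * (hi - lo) for lo, hi in pieces)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(total[off], full[off], rtol=1e-9, atol=1e-12)

    def test_band_outside_grid_rejected(self, var3_segments):
        _, segs = var3_segments
        fit = fit_mvar(segs, 3)
        sc = gc_spectral_from_model(fit, FS, 128)
        with pytest.raises(InvalidParameterError):
            integrate_band(sc, (150.0, 180.0))


class TestPerSubject:
    def test_six_matrices_per_stage_and_missing_records(self, var3_segments):
        _, segs = var3_segments
        es = make_epochset(segs)
        out = connectivity_per_subject(
            {"REM": es, "3": es, "W": None},
            MvgcSettings(order=3, n_freqs=256),
            subject_id="S1",
        )
        assert set(out.matrices) == {"REM", "3"}
        for stage in ("REM", "3"):
            assert set(out.matrices[stage]) == {"time", *DEFAULT_BANDS}
            assert out.integration[stage].passed
        assert "W" in out.missing

    def test_determinism(self, var3_segments):
        _, segs = var3_segments
        es = make_epochset(segs)
        a = connectivity_per_subject({"REM": es}, MvgcSettings(order=3, n_freqs=128))
        b = connectivity_per_subject({"REM": es}, MvgcSettings(order=3, n_freqs=128))
        assert np.array_equal(a.matrices["REM"]["time"].values,
                              b.matrices["REM"]["time"].values)
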