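"""Multivariate Granger-causality connectivity from epoched EEG.

One vector-autoregressive (VAR) model is fitted per subject x stage by
pooling the twelve 5-s segments as independent trials.  Directed causality
between every ordered electrode pair, conditional on the remaining
17 channels, is then computed in the time domain,

    F(j -> i | rest) = ln( Sigma'_ii / Sigma_ii ),

where Sigma_ii is channel i's innovation variance under the full model and
Sigma'_ii its variance under the reduced model that omits channel j, and in
the frequency domain via Geweke's spectral decomposition, whose average over
[0, Nyquist] recovers F.  Reduced models are not refit from data: they are
solved from the full model's autocovariance sequence (Whittle recursion) at
an order chosen from the autocovariance decay, which is what makes the
spectral integral match the time-domain value to high precision.

Frequency-band connectivity matrices (delta/theta/alpha/sigma/beta) are
bandwidth-normalized trapezoidal integrals of the spectral causality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _sla

from .bands import BandSet, DEFAULT_BANDS
from .epoching import EpochSet
from .errors import (
    EstimationError,
    InvalidParameterError,
    SpectralError,
    StabilityError,
)

__all__ = [
    "MVARModel",
    "ConnectivityMatrix",
    "SpectralConnectivity",
    "ConsistencyReport",
    "MvgcSettings",
    "SubjectConnectivity",
    "select_model_order",
    "fit_mvar",
    "companion_spectral_radius",
    "var_to_autocov",
    "autocov_to_var",
    "gc_time_matrix",
    "gc_time_from_model",
    "mvar_spectrum",
    "gc_spectral_matrix",
    "gc_spectral_from_model",
    "integrate_band",
    "check_integration",
    "connectivity_per_subject",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class MVARModel:
    """Order-p VAR model: x_t = sum_k A_k x_{t-k} + e_t, cov(e) = Sigma.

    ``coeffs`` is stacked (p, n, n) with ``coeffs[k][i, j]`` the influence of
    channel j at lag k+1 on channel i.  ``resid_cov`` is in uV^2.
    """

    order: int
    coeffs: np.ndarray
    resid_cov: np.ndarray
    n_obs_effective: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.resid_cov = np.asarray(self.resid_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise InvalidParameterError("coeffs must have shape (p, n, n)")
        if self.coeffs.shape[0] != self.order:
            raise InvalidParameterError("coeffs first axis must equal the model order")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeffs)


@dataclass
class ConnectivityMatrix:
    """Directed Granger causality for all ordered channel pairs.

    ``values[i, j]`` is the causality from channel i (source) to channel j
    (target), in natural-log units; the diagonal is fixed at zero and
    off-diagonal entries are non-negative after numerical clamping (the
    largest clamped magnitude is recorded in ``max_clamp``).
    """

    values: np.ndarray
    domain: str
    channel_labels: tuple[str, ...] = ()
    max_clamp: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise InvalidParameterError("connectivity matrix must be square")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class SpectralConnectivity:
    """Geweke spectral causality on a frequency grid.

    ``values[f, i, j]`` is the causality from channel i to channel j at
    ``freqs[f]`` (Hz); the grid spans [0, Nyquist] inclusive.
    """

    freqs: np.ndarray
    values: np.ndarray
    channel_labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")
        if self.values.shape[0] != self.freqs.size:
            raise InvalidParameterError("values first axis must match the frequency grid")


@dataclass
class ConsistencyReport:
    """Per-pair comparison of frequency-integrated vs time-domain causality."""

    rel_diff: np.ndarray
    max_rel_diff: float
    rel_tol: float
    passed: bool
    offending_pairs: tuple[tuple[int, int], ...] = ()
    f_floor: float = 0.01


# ---------------------------------------------------------------------------
# VAR estimation

def _stack_regression(segments: np.ndarray, p: int, trim: int):
    """Build the pooled multi-trial lag regression (per-segment demeaned).

    The first ``trim`` (>= p) samples of each segment serve only as lags so
    every candidate order sees the same response sample.
    Returns (Y, X) with Y (N, n) responses and X (N, n*p) lagged regressors,
    lag-major ordering [lag1 ch1..chn, lag2 ch1..chn, ...].
    """
    m, n, T = segments.shape
    if trim < p:
        raise InvalidParameterError("trim must be >= model order")
    if T <= trim:
        raise InvalidParameterError("segments shorter than the lag depth")
    seg = segments - segments.mean(axis=2, keepdims=True)
    rows = T - trim
    Y = np.empty((m * rows, n))
    X = np.empty((m * rows, n * p))
    for s in range(m):
        Y[s * rows:(s + 1) * rows] = seg[s, :, trim:].T
        for k in range(1, p + 1):
            X[s * rows:(s + 1) * rows, (k - 1) * n:k * n] = seg[s, :, trim - k:T - k].T
    return Y, X


def fit_mvar(es: EpochSet | np.ndarray, p: int) -> MVARModel:
    """Least-squares multi-trial VAR(p) fit of an EpochSet (or raw segments).

    Segments are treated as independent realizations: per-segment means are
    removed, the first p samples of each segment are used only as lags, and
    the regressions are stacked.  The residual covariance uses the degrees-
    of-freedom denominator N - n*p.
    """
    segments = es.segments if isinstance(es, EpochSet) else np.asarray(es, dtype=float)
    if p < 1:
        raise InvalidParameterError("model order must be >= 1")
    m, n, T = segments.shape
    Y, X = _stack_regression(segments, p, trim=p)
    N = Y.shape[0]
    if N <= n * p:
        raise InvalidParameterError(
            f"{N} observations cannot identify {n * p} regressors per equation"
        )
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < n * p:
        raise EstimationError(f"rank-deficient regressor matrix (rank {rank} < {n * p})")
    resid = Y - X @ B
    sigma = resid.T @ resid / (N - n * p)
    coeffs = np.stack([B[(k - 1) * n:k * n].T for k in range(1, p + 1)])
    model = MVARModel(order=p, coeffs=coeffs, resid_cov=sigma, n_obs_effective=N)
    if model.spectral_radius >= 1.0:
        raise EstimationError(
            f"estimated model unstable (spectral radius {model.spectral_radius:.4f})"
        )
    return model


def select_model_order(es: EpochSet | np.ndarray, p_max: int, criterion: str = "BIC") -> int:
    """Pick the VAR order in 1..p_max minimizing AIC or BIC.

    All candidates are scored on the common response sample obtained by
    trimming ``p_max`` lag samples from every segment, so the criteria are
    comparable across orders.  Ties resolve to the smallest order.
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise InvalidParameterError(f"criterion must be AIC or BIC, got {criterion!r}")
    segments = es.segments if isinstance(es, EpochSet) else np.asarray(es, dtype=float)
    m, n, T = segments.shape
    if p_max < 1:
        raise InvalidParameterError("p_max must be >= 1")
    total = m * (T - p_max)
    if total <= p_max * n:
        raise InvalidParameterError(
            f"p_max={p_max} leaves too few observations ({total}) for {p_max * n} regressors"
        )
    Y, X = _stack_regression(segments, p_max, trim=p_max)
    N = Y.shape[0]
    best_p, best_ic = 1, np.inf
    for p in range(1, p_max + 1):
        Xp = X[:, : n * p]
        B, _, _, _ = np.linalg.lstsq(Xp, Y, rcond=None)
        resid = Y - Xp @ B
        sigma = resid.T @ resid / N  # ML variant for the criteria
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k = p * n * n
        if criterion == "AIC":
            ic = logdet + 2.0 * k / N
        else:
            ic = logdet + math.log(N) * k / N
        if ic < best_ic - 1e-12:
            best_p, best_ic = p, ic
    return best_p


# ---------------------------------------------------------------------------
# autocovariance machinery

def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (0 for an empty model)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        return 0.0
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = coeffs.transpose(1, 0, 2).reshape(n, n * p)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def var_to_autocov(coeffs: np.ndarray, sigma: np.ndarray, n_lags: int) -> np.ndarray:
    """Autocovariance sequence Gamma_0..Gamma_{n_lags} of a stable VAR.

    Gamma_k = E[x_t x_{t-k}^T].  Gamma_0..Gamma_{p-1} come from the companion
    discrete Lyapunov equation; higher lags from the Yule-Walker recursion
    Gamma_k = sum_j A_j Gamma_{k-j}.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    p = coeffs.shape[0] if coeffs.size else 0
    if p == 0:
        G = np.zeros((n_lags + 1, n, n))
        G[0] = sigma
        return G
    rho = companion_spectral_radius(coeffs)
    if rho >= 1.0:
        raise StabilityError(f"VAR model unstable (spectral radius {rho:.4f})")
    npp = n * p
    comp = np.zeros((npp, npp))
    comp[:n] = coeffs.transpose(1, 0, 2).reshape(n, npp)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    Q = np.zeros((npp, npp))
    Q[:n, :n] = sigma
    method = "direct" if npp <= 80 else "bilinear"
    V = _sla.solve_discrete_lyapunov(comp, Q, method=method)
    V = 0.5 * (V + V.T)

    G = np.zeros((n_lags + 1, n, n))
    for k in range(min(p, n_lags + 1)):
        G[k] = V[:n, k * n:(k + 1) * n]
    G[0] = 0.5 * (G[0] + G[0].T)
    for k in range(p, n_lags + 1):
        # Gamma_k = sum_j A_j Gamma_{k-j}
        G[k] = np.einsum("jab,jbc->ac", coeffs, G[k - p:k][::-1] if p > 1 else G[k - 1:k])
    return G


def autocov_to_var(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the multivariate Yule-Walker system by Whittle's recursion.

    Given Gamma_0..Gamma_q returns (A, Sigma) of the order-q VAR whose
    autocovariance matches G, with A shaped (q, n, n).
    """
    G = np.asarray(G, dtype=float)
    q = G.shape[0] - 1
    n = G.shape[1]
    if q < 1:
        raise InvalidParameterError("need at least Gamma_0 and Gamma_1")
    GT = G.transpose(0, 2, 1)

    A = np.zeros((q, n, n))
    B = np.zeros((q, n, n))
    A[0] = np.linalg.solve(G[0].T, G[1].T).T          # Gamma_1 Gamma_0^-1
    B[0] = np.linalg.solve(G[0].T, GT[1].T).T         # Gamma_1^T Gamma_0^-1
    Vf = G[0] - A[0] @ GT[1]
    Vb = G[0] - B[0] @ G[1]

    for m in range(1, q):
        # forward innovation-vs-new-lag covariance
        delta = G[m + 1] - np.einsum("kab,kbc->ac", A[:m], G[1:m + 1][::-1])
        Am1 = np.linalg.solve(Vb.T, delta.T).T
        Bm1 = np.linalg.solve(Vf.T, delta).T
        A_new = A[:m] - np.einsum("ab,kbc->kac", Am1, B[:m][::-1])
        B_new = B[:m] - np.einsum("ab,kbc->kac", Bm1, A[:m][::-1])
        A[:m], A[m] = A_new, Am1
        B[:m], B[m] = B_new, Bm1
        Vf = Vf - Am1 @ delta.T
        Vb = Vb - Bm1 @ delta
        Vf = 0.5 * (Vf + Vf.T)
        Vb = 0.5 * (Vb + Vb.T)
    return A, Vf


def _choose_autocov_lags(model: MVARModel, decay_tol: float = 1e-7, max_lags: int = 192) -> int:
    """Lag horizon at which the model autocovariance has decayed to decay_tol."""
    rho = model.spectral_radius
    floor = max(2 * model.order, 8)
    if rho < 1e-3:
        return floor
    q = int(math.ceil(math.log(decay_tol) / math.log(rho)))
    return int(np.clip(q, floor, max_lags))


# ---------------------------------------------------------------------------
# time-domain causality

def gc_time_from_model(
    model: MVARModel,
    n_lags: int | None = None,
    channel_labels: tuple[str, ...] = (),
    mode: str = "conditional",
) -> ConnectivityMatrix:
    """Time-domain Granger causality of a (fitted) VAR model.

    In ``conditional`` mode (default), F(j -> i | rest) compares the full
    model against the reduced model over the other 18 channels, solved from
    the full model's autocovariance.  In ``bivariate`` mode each ordered
    pair is assessed on its own marginal pair process (indirect influences
    through third channels then show up as causality).
    """
    if mode not in ("conditional", "bivariate"):
        raise InvalidParameterError(f"mode must be conditional or bivariate, got {mode!r}")
    n = model.n_channels
    if n_lags is None:
        n_lags = _choose_autocov_lags(model)
    G = var_to_autocov(model.coeffs, model.resid_cov, n_lags)
    full_var = np.diag(model.resid_cov)
    if np.any(full_var <= 0):
        raise SpectralError("non-positive full-model residual variance")

    F = np.zeros((n, n))
    if mode == "conditional":
        for j in range(n):
            keep = [i for i in range(n) if i != j]
            Gr = G[np.ix_(range(n_lags + 1), keep, keep)]
            _, sig_r = autocov_to_var(Gr)
            ratio = np.diag(sig_r) / full_var[keep]
            if np.any(ratio <= 0):
                raise SpectralError(f"non-positive reduced residual variance (source {j})")
            F[j, keep] = np.log(ratio)
    else:
        for i in range(n):
            # univariate reduced model of the target alone
            Gi = G[:, i:i + 1, i:i + 1]
            _, sig_i = autocov_to_var(Gi)
            for j in range(n):
                if j == i:
                    continue
                pair = [i, j]
                Gp = G[np.ix_(range(n_lags + 1), pair, pair)]
                _, sig_p = autocov_to_var(Gp)
                if sig_p[0, 0] <= 0 or sig_i[0, 0] <= 0:
                    raise SpectralError(f"non-positive residual variance (pair {j}->{i})")
                F[j, i] = math.log(sig_i[0, 0] / sig_p[0, 0])
    max_clamp = float(max(0.0, -F.min()))
    F = np.clip(F, 0.0, None)
    np.fill_diagonal(F, 0.0)
    return ConnectivityMatrix(
        values=F, domain="time", channel_labels=tuple(channel_labels),
        max_clamp=max_clamp,
        meta={"order": model.order, "n_lags": n_lags, "mode": mode},
    )


def gc_time_matrix(es: EpochSet, p: int, mode: str = "conditional") -> ConnectivityMatrix:
    """Fit a VAR(p) to the EpochSet and return the time-domain GC matrix."""
    model = fit_mvar(es, p)
    return gc_time_from_model(model, channel_labels=tuple(es.channel_labels), mode=mode)


# ---------------------------------------------------------------------------
# frequency domain

def _poly_eval(coeffs: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """A(lambda) = I - sum_k A_k exp(-2 pi i lambda k / fs), shape (F, n, n).

    Uses an rFFT when the grid is the uniform [0, Nyquist] grid and long
    enough to hold the coefficient sequence, else direct evaluation.
    """
    p, n, _ = coeffs.shape if coeffs.size else (0, coeffs.shape[1], coeffs.shape[2])
    F = freqs.size
    eye = np.eye(n)
    if p == 0:
        return np.broadcast_to(eye, (F, n, n)).astype(complex).copy()
    uniform = F >= 2 and np.allclose(freqs, np.linspace(0, fs / 2, F))
    nfft = 2 * (F - 1)
    if uniform and nfft >= p + 1:
        buf = np.zeros((nfft, n, n))
        buf[1:p + 1] = coeffs
        return eye - np.fft.rfft(buf, axis=0)[:F]
    phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)  # (F, p)
    return eye - np.einsum("fk,kij->fij", phase, coeffs)


def mvar_spectrum(
    model: MVARModel, freqs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Transfer function H(lambda) and cross-spectral density S(lambda).

    S is one-sided in the sense that integrating S * 2/fs over [0, fs/2]
    recovers the process covariance.  Returns (H, S), each (F, n, n) complex.
    """
    freqs = np.asarray(freqs, dtype=float)
    if model.coeffs.size and model.spectral_radius >= 1.0:
        raise StabilityError("cannot evaluate the spectrum of an unstable model")
    A = _poly_eval(model.coeffs, freqs, fs)
    cond = np.linalg.cond(A)
    if np.any(~np.isfinite(cond)) or np.max(cond) > 1e12:
        raise SpectralError("A(lambda) numerically singular on the grid")
    H = np.linalg.inv(A)
    S = H @ model.resid_cov @ H.conj().transpose(0, 2, 1)
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return H, S


def _spectral_sources(G, sigma, H, freqs, fs):
    """Spectral causality from every source into every target of one system.

    ``G``/``sigma``/``H`` describe the (sub)system: autocovariance stack,
    innovation covariance, transfer function on ``freqs``.  Returns the
    (F, n, n) array of f(source -> target)(lambda).
    """
    q = G.shape[0] - 1
    n = sigma.shape[0]
    floor = np.finfo(float).tiny
    vals = np.zeros((freqs.size, n, n))
    for j in range(n):
        keep = [i for i in range(n) if i != j]
        Gr = G[np.ix_(range(q + 1), keep, keep)]
        Ar, _ = autocov_to_var(Gr)
        Br = _poly_eval(Ar, freqs, fs)
        Phi = Br @ H[:, keep, :]
        total = np.einsum("fik,kl,fil->fi", Phi, sigma, Phi.conj()).real
        total = np.maximum(total, floor)
        sig_kk = np.diag(sigma)[keep]
        if np.any(sig_kk <= 0):
            raise SpectralError("non-positive innovation variance")
        C = sigma[:, keep] / sig_kk[None, :]
        proj = np.einsum("fpk,kp->fp", Phi, C)
        own = np.maximum(np.abs(proj) ** 2 * sig_kk[None, :], floor)
        vals[:, j, keep] = np.clip(np.log(total) - np.log(own), 0.0, None)
    return vals


def gc_spectral_from_model(
    model: MVARModel,
    fs: float,
    n_freqs: int = 1024,
    n_lags: int | None = None,
    channel_labels: tuple[str, ...] = (),
    mode: str = "conditional",
) -> SpectralConnectivity:
    """Geweke conditional spectral causality f(j -> i | rest)(lambda).

    Implementation follows the classical two-model construction with the
    innovation-partition refinement: the reduced model (channels without the
    source j) is solved from the full model's autocovariance, and its
    inverse transfer function maps the full-model spectral factors onto the
    reduced innovation process x~ of each target.  The causality at each
    frequency is the log ratio of x~'s total spectrum to the part driven by
    the target's own full-model innovation (with the instantaneous
    correlation of the other innovations partialized out).  This is the
    variant whose average over [0, Nyquist] recovers the time-domain value
    exactly; the naive "total minus source contribution" denominator does
    not integrate correctly in the presence of confounding.
    """
    if n_freqs < 64:
        raise InvalidParameterError("n_freqs must be >= 64")
    if mode not in ("conditional", "bivariate"):
        raise InvalidParameterError(f"mode must be conditional or bivariate, got {mode!r}")
    n = model.n_channels
    sigma = model.resid_cov
    if n_lags is None:
        n_lags = _choose_autocov_lags(model)
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    G = var_to_autocov(model.coeffs, model.resid_cov, n_lags)

    if mode == "conditional":
        H, _ = mvar_spectrum(model, freqs, fs)
        vals = _spectral_sources(G, sigma, H, freqs, fs)
    else:
        vals = np.zeros((n_freqs, n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pair = [i, j]
                Gp = G[np.ix_(range(n_lags + 1), pair, pair)]
                Ap, Sp = autocov_to_var(Gp)
                Hp = np.linalg.inv(_poly_eval(Ap, freqs, fs))
                sub = _spectral_sources(Gp, Sp, Hp, freqs, fs)
                vals[:, i, j] = sub[:, 0, 1]
                vals[:, j, i] = sub[:, 1, 0]
    return SpectralConnectivity(
        freqs=freqs, values=vals, channel_labels=tuple(channel_labels),
        meta={"order": model.order, "n_lags": n_lags, "fs": fs, "mode": mode},
    )


def gc_spectral_matrix(
    es: EpochSet, p: int, n_freqs: int = 1024, fs: float | None = None
) -> SpectralConnectivity:
    """Fit a VAR(p) to the EpochSet and return the spectral GC on a uniform grid."""
    model = fit_mvar(es, p)
    return gc_spectral_from_model(
        model, fs if fs is not None else es.fs, n_freqs,
        channel_labels=tuple(es.channel_labels),
    )


def integrate_band(sc: SpectralConnectivity, band: tuple[float, float], name: str = "") -> ConnectivityMatrix:
    """Bandwidth-normalized trapezoidal integral of f(lambda) over ``band``.

    The spectral causality is treated as piecewise linear on its grid; the
    band edges are inserted by interpolation, which makes band integrals
    exactly additive across contiguous bands.
    """
    lo, hi = float(band[0]), float(band[1])
    fmin, fmax = sc.freqs[0], sc.freqs[-1]
    lo_c, hi_c = max(lo, fmin), min(hi, fmax)
    if not hi_c > lo_c:
        raise InvalidParameterError(f"band [{lo}, {hi}) does not overlap the grid")
    inside = (sc.freqs > lo_c) & (sc.freqs < hi_c)
    grid = np.concatenate(([lo_c], sc.freqs[inside], [hi_c]))
    n = sc.values.shape[1]
    flat = sc.values.reshape(sc.freqs.size, -1)
    interp = np.empty((grid.size, flat.shape[1]))
    for c in range(flat.shape[1]):
        interp[:, c] = np.interp(grid, sc.freqs, flat[:, c])
    integral = np.trapezoid(interp, grid, axis=0).reshape(n, n)
    vals = integral / (hi_c - lo_c)
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(
        values=vals, domain=name or f"band[{lo},{hi})",
        channel_labels=sc.channel_labels,
        meta={"band": (lo, hi), "effective_band": (lo_c, hi_c), **sc.meta},
    )


def check_integration(
    sc: SpectralConnectivity, tm: ConnectivityMatrix, rel_tol: float = 0.01
) -> ConsistencyReport:
    """Compare the full-range frequency average of f with the time-domain F.

    Relative differences are evaluated only for pairs with F above a small
    floor (0.01): tiny causalities are dominated by clamping noise.
    """
    full = integrate_band(sc, (sc.freqs[0], sc.freqs[-1]), name="full")
    F = tm.values
    mask = F > 0.01
    np.fill_diagonal(mask, False)
    rel = np.zeros_like(F)
    rel[mask] = np.abs(full.values[mask] - F[mask]) / F[mask]
    max_rel = float(rel[mask].max()) if mask.any() else 0.0
    offending = tuple(zip(*np.where((rel > rel_tol) & mask))) if mask.any() else ()
    return ConsistencyReport(
        rel_diff=rel, max_rel_diff=max_rel, rel_tol=rel_tol,
        passed=max_rel <= rel_tol,
        offending_pairs=tuple((int(a), int(b)) for a, b in offending),
    )


# ---------------------------------------------------------------------------
# per-subject orchestration

@dataclass
class MvgcSettings:
    """Connectivity-stage configuration."""

    order: int | str = "auto"       # fixed order, or "auto" for criterion-based
    criterion: str = "BIC"
    p_max: int = 20
    n_freqs: int = 1024
    rel_tol: float = 0.01
    mode: str = "conditional"       # or "bivariate" (pairwise marginal GC)
    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)


@dataclass
class SubjectConnectivity:
    """All connectivity matrices of one subject (time + bands, per stage)."""

    subject_id: str
    matrices: dict  # stage -> {domain -> ConnectivityMatrix}
    integration: dict  # stage -> ConsistencyReport
    missing: dict  # stage -> reason string
    provenance: dict


def connectivity_per_subject(
    es_by_stage: dict[str, EpochSet],
    settings: MvgcSettings | None = None,
    subject_id: str = "",
) -> SubjectConnectivity:
    """Compute the six matrices (time + five bands) for every available stage.

    Stage-level failures are recorded under ``missing`` rather than raised,
    so one unusable stage never loses the rest of the subject.
    """
    settings = settings or MvgcSettings()
    matrices: dict[str, dict[str, ConnectivityMatrix]] = {}
    integration: dict[str, ConsistencyReport] = {}
    missing: dict[str, str] = {}
    orders: dict[str, int] = {}
    for stage, es in es_by_stage.items():
        if es is None:
            missing[stage] = "no epochs available"
            continue
        try:
            if settings.order == "auto":
                p = select_model_order(es, settings.p_max, settings.criterion)
            else:
                p = int(settings.order)
            model = fit_mvar(es, p)
            labels = tuple(es.channel_labels)
            tm = gc_time_from_model(model, channel_labels=labels, mode=settings.mode)
            sc = gc_spectral_from_model(
                model, es.fs, settings.n_freqs, channel_labels=labels,
                mode=settings.mode,
            )
            entry = {"time": tm}
            for name in settings.bands:
                entry[name] = integrate_band(sc, settings.bands[name], name=name)
            matrices[stage] = entry
            integration[stage] = check_integration(sc, tm, settings.rel_tol)
            orders[stage] = p
        except Exception as exc:  # recorded, not fatal
            missing[stage] = f"{type(exc).__name__}: {exc}"
    return SubjectConnectivity(
        subject_id=subject_id,
        matrices=matrices,
        integration=integration,
        missing=missing,
        provenance={
            "orders": orders,
            "criterion": settings.criterion,
            "n_freqs": settings.n_freqs,
            "mode": settings.mode,
        },
    )
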