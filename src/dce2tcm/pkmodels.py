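"""Tracer-kinetic forward models and per-curve fitting.

Two models link the tissue contrast-agent concentration C(t) (mM) to the
plasma input Cp(t):

* the standard Tofts model, one well-mixed extravascular extracellular
  compartment,

      C(t) = Ktrans * integral_0^t Cp(tau) exp(-(t - tau) kep) dtau,

  with Ktrans the plasma-to-EES transfer constant (min^-1), kep = Ktrans/ve
  the efflux rate and ve the EES volume fraction;

* a two-tissue compartment model (2TCM) in which each voxel contains one
  fast and one slow exchanging compartment, giving a two-exponential kernel

      C(t) = K1trans * [Cp (x) exp(-kep1 t)] + K2trans * [Cp (x) exp(-kep2 t)]

  ((x) = convolution).  For fitting, the 2TCM is reparameterised in an
  asymmetric form (K1trans, kep1, eps, lam) with K2trans = eps * K1trans and
  kep2 = kep1 + lam, lam >= 0, which removes the compartment-relabelling
  degeneracy inside the optimizer.  The conventional amplitude ordering
  (K1trans = the larger amplitude, with its paired rate as kep1) is restored
  afterwards by :func:`canonicalize_2tcm`, so reported K1trans/kep1 always
  describe the dominant (usually fast) compartment.

All rates are in min^-1 and times in minutes.  The convolution with the
exponential kernel is computed exactly for a piecewise-linear interpolant of
Cp (a per-interval recursive update), which is accurate at the coarse
(~8 s) sampling of clinical dynamic series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .aif import AIF

__all__ = [
    "ToftsParams",
    "TwoTCMParams",
    "FitResult",
    "exp_convolve",
    "tofts_forward",
    "twotcm_forward",
    "canonicalize_2tcm",
    "rmse",
    "fit_tofts",
    "fit_2tcm",
    "ToftsModel",
    "TwoCompartmentModel",
]

# Bounds chosen for physiological generosity without flat tails.
DEFAULT_KTRANS_BOUNDS = (0.0, 5.0)  # min^-1
DEFAULT_KEP_BOUNDS = (0.0, 10.0)  # min^-1
DEFAULT_EPS_BOUNDS = (0.0, 100.0)  # dimensionless amplitude ratio
DEFAULT_LAM_BOUNDS = (0.0, 10.0)  # min^-1

_FIT_TOL = 1e-10
_MAX_NFEV = 500


@dataclass(frozen=True)
class ToftsParams:
    """Standard Tofts parameters (rates in min^-1)."""

    ktrans: float
    kep: float

    @property
    def ve(self) -> float:
        """EES volume fraction ve = Ktrans/kep (nan when kep == 0)."""
        return self.ktrans / self.kep if self.kep > 0 else math.nan

    def __post_init__(self):
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be >= 0, got {self.ktrans}")
        if self.kep < 0:
            raise ValueError(f"kep must be >= 0, got {self.kep}")


@dataclass(frozen=True)
class TwoTCMParams:
    """Two-tissue compartment parameters (rates in min^-1).

    Stored as the four physical rates.  In fit space the record satisfies
    k2trans = eps * k1trans and kep2 = kep1 + lam with lam >= 0; after
    :func:`canonicalize_2tcm` the amplitudes satisfy k1trans >= k2trans and
    ``lam`` (= kep2 - kep1) may be negative.
    """

    k1trans: float
    kep1: float
    k2trans: float
    kep2: float

    def __post_init__(self):
        for name in ("k1trans", "kep1", "k2trans", "kep2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def from_fit_space(cls, k1trans: float, kep1: float, eps: float, lam: float) -> "TwoTCMParams":
        if lam < 0:
            raise ValueError(f"lam must be >= 0 in fit space, got {lam}")
        if eps < 0:
            raise ValueError(f"eps must be >= 0, got {eps}")
        return cls(k1trans=k1trans, kep1=kep1, k2trans=eps * k1trans, kep2=kep1 + lam)

    @property
    def eps(self) -> float:
        """Amplitude ratio K2trans/K1trans (nan when K1trans == 0)."""
        return self.k2trans / self.k1trans if self.k1trans > 0 else math.nan

    @property
    def lam(self) -> float:
        """Rate offset kep2 - kep1."""
        return self.kep2 - self.kep1

    @property
    def ve1(self) -> float:
        return self.k1trans / self.kep1 if self.kep1 > 0 else math.nan

    @property
    def ve2(self) -> float:
        return self.k2trans / self.kep2 if self.kep2 > 0 else math.nan


@dataclass
class FitResult:
    """Result of a single-curve least-squares fit."""

    params: "ToftsParams | TwoTCMParams"
    rmse: float
    converged: bool
    n_iter: int
    residuals: np.ndarray = field(repr=False)


def _check_times(times_min: np.ndarray) -> np.ndarray:
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times_min must be a 1-D array with at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times_min must be strictly increasing")
    return t


def exp_convolve(cp: np.ndarray, times_min: np.ndarray, k: float) -> np.ndarray:
    """Convolve a sampled curve with exp(-k t), exactly for linear interpolation.

    Returns F(t_n) = integral_0^{t_n} cp(tau) exp(-k (t_n - tau)) dtau on the
    sample grid, treating ``cp`` as piecewise linear between samples.  For
    k = 0 this reduces to the cumulative trapezoid integral of ``cp``.

    Parameters
    ----------
    cp : array, shape (n,)
        Input curve sampled at ``times_min``.
    times_min : array, shape (n,)
        Strictly increasing sample times (minutes).
    k : float
        Exponential rate (min^-1), must be >= 0.
    """
    t = _check_times(times_min)
    c = np.asarray(cp, dtype=float)
    if c.shape != t.shape:
        raise ValueError("cp and times_min must have the same shape")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return cumulative_trapezoid(c, t, initial=0.0)

    dt = np.diff(t)
    kdt = k * dt
    # Per-interval integral of (c0 + slope*u) exp(-k (dt - u)) du over [0, dt]:
    #   I = c0 * A + slope * B,  A = (1 - e^{-k dt})/k,  B = (dt - A)/k.
    A = -np.expm1(-kdt) / k
    small = kdt < 1e-5
    with np.errstate(invalid="ignore", divide="ignore"):
        B = np.where(small, dt**2 / 2 - k * dt**3 / 6, (dt - A) / k)
    slope = np.diff(c) / dt
    inc = c[:-1] * A + slope * B

    out = np.empty_like(c)
    out[0] = 0.0
    if k * (t[-1] - t[0]) < 600.0:
        # F(t_n) = e^{-k t_n} * sum_{j<=n} inc_j e^{k t_j}; safe within exp range.
        w = np.exp(k * (t[1:] - t[0]))
        out[1:] = np.cumsum(inc * w) / w
    else:  # decay so fast that e^{k t} would overflow; sequential update
        E = np.exp(-kdt)
        acc = 0.0
        for i in range(dt.size):
            acc = acc * E[i] + inc[i]
            out[i + 1] = acc
    return out


def tofts_forward(p: ToftsParams, aif: AIF) -> np.ndarray:
    """Tissue concentration predicted by the standard Tofts model (mM)."""
    return p.ktrans * exp_convolve(aif.cp_mM, aif.times_min, p.kep)


def twotcm_forward(p: TwoTCMParams, aif: AIF, form: str = "two_term") -> np.ndarray:
    """Tissue concentration predicted by the 2TCM (mM).

    ``form="two_term"`` evaluates the two-exponential sum from the physical
    rates (k1trans, kep1, k2trans, kep2); ``form="factored"`` evaluates the
    asymmetric factored kernel via (k1trans, kep1, eps, lam).  The two routes
    are algebraically identical and agree to machine precision.
    """
    cp, t = aif.cp_mM, aif.times_min
    if form == "two_term":
        return p.k1trans * exp_convolve(cp, t, p.kep1) + p.k2trans * exp_convolve(cp, t, p.kep2)
    if form == "factored":
        eps = p.k2trans / p.k1trans if p.k1trans > 0 else 0.0
        lam = p.kep2 - p.kep1
        if lam < 0:
            raise ValueError("factored form requires kep2 >= kep1 (fit-space record)")
        base = exp_convolve(cp, t, p.kep1)
        extra = exp_convolve(cp, t, p.kep1 + lam)
        return p.k1trans * (base + eps * extra)
    raise ValueError(f"unknown form {form!r}")


def canonicalize_2tcm(raw: TwoTCMParams) -> TwoTCMParams:
    """Order compartments so K1trans is the larger amplitude.

    The fit-space parameterisation leaves which compartment carries the
    larger amplitude arbitrary; maps and statistics use the convention
    K1trans = max(K1trans, K2trans) with its paired rate as kep1.  Amplitude
    ties are broken by assigning the larger kep (the fast compartment) to
    position 1.  Idempotent.
    """
    a1, r1, a2, r2 = raw.k1trans, raw.kep1, raw.k2trans, raw.kep2
    if (a2 > a1) or (a2 == a1 and r2 > r1):
        a1, r1, a2, r2 = a2, r2, a1, r1
    return TwoTCMParams(k1trans=a1, kep1=r1, k2trans=a2, kep2=r2)


def rmse(c: np.ndarray, fit_curve: np.ndarray) -> float:
    """Root-mean-square error between a measured and a fitted curve (mM)."""
    c = np.asarray(c, dtype=float)
    f = np.asarray(fit_curve, dtype=float)
    if c.shape != f.shape:
        raise ValueError(f"curve length mismatch: {c.shape} vs {f.shape}")
    return float(np.sqrt(np.mean((c - f) ** 2)))


# ---------------------------------------------------------------------------
# fitting


def _tofts_residual(theta, c, cp, t):
    ktrans, kep = theta
    return ktrans * exp_convolve(cp, t, kep) - c


def _twotcm_curve_fit_space(theta, cp, t):
    k1, kep1, eps, lam = theta
    return k1 * (exp_convolve(cp, t, kep1) + eps * exp_convolve(cp, t, kep1 + lam))


def fit_tofts(
    c: np.ndarray,
    aif: AIF,
    init: ToftsParams | None = None,
    bounds: tuple = (DEFAULT_KTRANS_BOUNDS, DEFAULT_KEP_BOUNDS),
) -> FitResult:
    """Bounded least-squares fit of the standard Tofts model to one curve."""
    c = np.asarray(c, dtype=float)
    cp, t = np.asarray(aif.cp_mM, float), np.asarray(aif.times_min, float)
    if c.shape != t.shape:
        raise ValueError("curve and AIF must share the time grid")
    if np.all(c == 0):
        return FitResult(ToftsParams(0.0, 0.0), 0.0, True, 0, np.zeros_like(c))

    if init is None:
        kep0 = 0.5
        ref = exp_convolve(cp, t, kep0)
        peak = float(np.max(ref))
        kt0 = float(np.clip(np.max(c) / peak if peak > 0 else 0.1, 1e-3, bounds[0][1]))
        init = ToftsParams(kt0, kep0)
    lo = [bounds[0][0], bounds[1][0]]
    hi = [bounds[0][1], bounds[1][1]]
    x0 = np.clip([init.ktrans, init.kep], lo, hi)
    sol = least_squares(
        _tofts_residual,
        x0,
        bounds=(lo, hi),
        args=(c, cp, t),
        method="trf",
        ftol=_FIT_TOL,
        xtol=_FIT_TOL,
        gtol=_FIT_TOL,
        max_nfev=_MAX_NFEV,
    )
    params = ToftsParams(float(sol.x[0]), float(sol.x[1]))
    res = sol.fun
    return FitResult(params, float(np.sqrt(np.mean(res**2))), bool(sol.status > 0), int(sol.nfev), res)


def _jittered_starts(base: np.ndarray, rng: np.random.Generator, n: int, lo, hi):
    starts = []
    for _ in range(n):
        f = rng.uniform([0.5, 0.5, 0.0, 0.2], [1.5, 1.5, 1.0, 3.0])
        x = np.array([base[0] * f[0], base[1] * f[1], f[2], f[3]])
        starts.append(np.clip(x, lo, hi))
    return starts


def fit_2tcm(
    c: np.ndarray,
    aif: AIF,
    bounds: tuple = (
        DEFAULT_KTRANS_BOUNDS,
        DEFAULT_KEP_BOUNDS,
        DEFAULT_EPS_BOUNDS,
        DEFAULT_LAM_BOUNDS,
    ),
    n_jitter: int = 3,
    seed: int = 0,
) -> FitResult:
    """Multistart bounded least-squares fit of the 2TCM to one curve.

    Fits in the asymmetric space (K1trans, kep1, eps, lam >= 0).  The start
    list contains the Tofts solution with eps = 0 — so the returned fit can
    never be worse than the nested Tofts fit — plus a mildly perturbed copy
    and ``n_jitter`` seeded random starts; the lowest-SSE candidate wins and
    is returned in canonical (amplitude-ordered) form.
    """
    c = np.asarray(c, dtype=float)
    cp, t = np.asarray(aif.cp_mM, float), np.asarray(aif.times_min, float)
    if c.shape != t.shape:
        raise ValueError("curve and AIF must share the time grid")
    if np.all(c == 0):
        return FitResult(TwoTCMParams(0.0, 0.0, 0.0, 0.0), 0.0, True, 0, np.zeros_like(c))

    lo = np.array([bounds[0][0], bounds[1][0], bounds[2][0], bounds[3][0]])
    hi = np.array([bounds[0][1], bounds[1][1], bounds[2][1], bounds[3][1]])

    tofts = fit_tofts(c, aif, bounds=(bounds[0], bounds[1]))
    base = np.array([max(tofts.params.ktrans, 1e-6), max(tofts.params.kep, 1e-3), 0.0, 1.0])
    x_tofts = np.clip(base, lo, hi)
    starts = [x_tofts, np.clip(base + [0.0, 0.0, 0.1, 0.0], lo, hi)]
    rng = np.random.default_rng(seed)
    starts += _jittered_starts(base, rng, n_jitter, lo, hi)

    def resid(theta):
        return _twotcm_curve_fit_space(theta, cp, t) - c

    # The un-optimized Tofts point is itself a candidate: with eps = 0 its
    # residuals equal the Tofts residuals exactly, guaranteeing nesting.
    best_x, best_res = x_tofts, resid(x_tofts)
    best_sse = float(best_res @ best_res)
    best_status, best_nfev = (1 if tofts.converged else 0), tofts.n_iter
    for x0 in starts:
        sol = least_squares(
            resid,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=_FIT_TOL,
            xtol=_FIT_TOL,
            gtol=_FIT_TOL,
            max_nfev=_MAX_NFEV,
        )
        sse = float(sol.fun @ sol.fun)
        if sse < best_sse:
            best_x, best_res, best_sse = sol.x, sol.fun, sse
            best_status, best_nfev = sol.status, best_nfev + sol.nfev
    params = canonicalize_2tcm(TwoTCMParams.from_fit_space(*best_x))
    return FitResult(
        params,
        float(np.sqrt(np.mean(best_res**2))),
        bool(best_status > 0),
        int(best_nfev),
        best_res,
    )


# ---------------------------------------------------------------------------
# estimator interface


class _CurveFitterBase(BaseEstimator):
    """Shared batch-fitting machinery for the per-curve kinetic models."""

    def _validate_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be (n_curves, n_frames)")
        if self.aif is None:
            raise ValueError("an AIF must be supplied at construction")
        if X.shape[1] != np.asarray(self.aif.times_min).size:
            raise ValueError("curves and AIF must share the time grid")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X


class ToftsModel(_CurveFitterBase):
    """Standard Tofts model fitted independently to each concentration curve.

    Parameters
    ----------
    aif : AIF
        Plasma input function on the same time grid as the curves.
    ktrans_bounds, kep_bounds : (low, high)
        Box constraints in min^-1.

    Attributes
    ----------
    ktrans_, kep_, ve_ : ndarray, shape (n_curves,)
    rmse_ : ndarray, shape (n_curves,)
        Per-curve root-mean-square fit error (mM).
    converged_ : ndarray of bool
    """

    def __init__(self, aif: AIF | None = None, ktrans_bounds=DEFAULT_KTRANS_BOUNDS, kep_bounds=DEFAULT_KEP_BOUNDS):
        self.aif = aif
        self.ktrans_bounds = ktrans_bounds
        self.kep_bounds = kep_bounds

    def fit(self, X, y=None):
        X = self._validate_X(X)
        n = X.shape[0]
        self.ktrans_ = np.empty(n)
        self.kep_ = np.empty(n)
        self.ve_ = np.empty(n)
        self.rmse_ = np.empty(n)
        self.converged_ = np.empty(n, dtype=bool)
        for i in range(n):
            r = fit_tofts(X[i], self.aif, bounds=(self.ktrans_bounds, self.kep_bounds))
            self.ktrans_[i] = r.params.ktrans
            self.kep_[i] = r.params.kep
            self.ve_[i] = r.params.ve
            self.rmse_[i] = r.rmse
            self.converged_[i] = r.converged
        return self

    def predict(self, X=None):
        """Fitted model curves for the training data, shape (n_curves, n_frames)."""
        if not hasattr(self, "ktrans_"):
            raise ValueError("call fit first")
        return np.stack(
            [tofts_forward(ToftsParams(kt, kep), self.aif) for kt, kep in zip(self.ktrans_, self.kep_)]
        )


class TwoCompartmentModel(_CurveFitterBase):
    """Two-tissue compartment model fitted independently to each curve.

    Fitted attributes (each shape ``(n_curves,)``) hold the canonical,
    amplitude-ordered parameters: ``k1trans_``/``kep1_`` describe the
    dominant compartment, ``k2trans_``/``kep2_`` the minor one, plus
    ``ve1_``, ``ve2_``, ``rmse_`` and ``converged_``.
    """

    def __init__(
        self,
        aif: AIF | None = None,
        ktrans_bounds=DEFAULT_KTRANS_BOUNDS,
        kep_bounds=DEFAULT_KEP_BOUNDS,
        eps_bounds=DEFAULT_EPS_BOUNDS,
        lam_bounds=DEFAULT_LAM_BOUNDS,
        n_jitter: int = 3,
        seed: int = 0,
    ):
        self.aif = aif
        self.ktrans_bounds = ktrans_bounds
        self.kep_bounds = kep_bounds
        self.eps_bounds = eps_bounds
        self.lam_bounds = lam_bounds
        self.n_jitter = n_jitter
        self.seed = seed

    def fit(self, X, y=None):
        X = self._validate_X(X)
        n = X.shape[0]
        for name in ("k1trans_", "kep1_", "k2trans_", "kep2_", "ve1_", "ve2_", "rmse_"):
            setattr(self, name, np.empty(n))
        self.converged_ = np.empty(n, dtype=bool)
        bounds = (self.ktrans_bounds, self.kep_bounds, self.eps_bounds, self.lam_bounds)
        for i in range(n):
            # per-curve seed keeps results independent of batch order
            r = fit_2tcm(X[i], self.aif, bounds=bounds, n_jitter=self.n_jitter, seed=(self.seed + i) % 2**31)
            p = r.params
            self.k1trans_[i], self.kep1_[i] = p.k1trans, p.kep1
            self.k2trans_[i], self.kep2_[i] = p.k2trans, p.kep2
            self.ve1_[i], self.ve2_[i] = p.ve1, p.ve2
            self.rmse_[i] = r.rmse
            self.converged_[i] = r.converged
        return self

    def predict(self, X=None):
        if not hasattr(self, "k1trans_"):
            raise ValueError("call fit first")
        return np.stack(
            [
                twotcm_forward(TwoTCMParams(a1, r1, a2, r2), self.aif)
                for a1, r1, a2, r2 in zip(self.k1trans_, self.kep1_, self.k2trans_, self.kep2_)
            ]
        )
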