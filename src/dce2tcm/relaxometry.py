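"""Variable-flip-angle T1 mapping and SPGR signal <-> concentration conversion.

The spoiled gradient-echo (SPGR) steady-state signal at flip angle alpha and
repetition time TR is

    S = M0 sin(alpha) (1 - E1) / (1 - E1 cos(alpha)),   E1 = exp(-TR/T1).

Pre-contrast T1 (T10) is estimated from a multi-flip-angle acquisition by
the classic linearisation S/sin(alpha) = E1 * S/tan(alpha) + M0 (1 - E1)
(slope = E1), optionally polished by a nonlinear SPGR fit.

A gadolinium agent shortens T1 in proportion to its concentration,
R1(t) = 1/T1(t) = R10 + r1 * C(t) with relaxivity r1 (s^-1 mM^-1), so the
dynamic signal is converted to concentration by inverting the SPGR equation
for T1(t) frame by frame, with M0 calibrated from the pre-contrast
(baseline) frames and the measured T10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

# r1 of gadobenate dimeglumine at 3 T; every analysis here is a round trip
# through the same constant, so results do not hinge on its exact value.
DEFAULT_RELAXIVITY_R1 = 5.5  # s^-1 mM^-1
DEFAULT_BASELINE_FRAMES = 4

__all__ = [
    "DynamicSeries",
    "VFASeries",
    "T1Map",
    "ConcentrationSeries",
    "spgr_signal",
    "VFAT1Mapper",
    "fit_vfa_t1",
    "signal_to_concentration",
    "DEFAULT_RELAXIVITY_R1",
    "DEFAULT_BASELINE_FRAMES",
]


@dataclass
class DynamicSeries:
    """4-D dynamic signal (rows, cols, slices, frames) with acquisition metadata."""

    signal: np.ndarray
    times_min: np.ndarray  # frame times, minutes, t=0 at first frame
    tr_ms: float
    flip_deg: float
    baseline_frames: int = DEFAULT_BASELINE_FRAMES

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.signal.shape[-1] != self.times_min.size:
            raise ValueError("last signal axis must match number of frame times")
        if self.signal.shape[-1] < 2:
            raise ValueError("need at least 2 frames")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if not (0 < self.flip_deg <= 90):
            raise ValueError("flip_deg must be in (0, 90]")
        if not (1 <= self.baseline_frames < self.signal.shape[-1]):
            raise ValueError("baseline_frames must be >= 1 and fewer than total frames")


@dataclass
class VFASeries:
    """Multi-flip-angle pre-contrast signal, last axis = flip angle."""

    signal: np.ndarray
    flip_angles_deg: np.ndarray
    tr_ms: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        if self.flip_angles_deg.ndim != 1 or np.unique(self.flip_angles_deg).size < 2:
            raise ValueError("need >= 2 distinct flip angles")
        if np.any(self.flip_angles_deg <= 0) or np.any(self.flip_angles_deg > 90):
            raise ValueError("flip angles must be in (0, 90] degrees")
        if self.signal.shape[-1] != self.flip_angles_deg.size:
            raise ValueError("last signal axis must match number of flip angles")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")


@dataclass
class T1Map:
    """Voxelwise T1 estimate; invalid voxels are flagged, never silently zero."""

    t1_s: np.ndarray
    m0: np.ndarray
    valid_mask: np.ndarray


@dataclass
class ConcentrationSeries:
    """Voxelwise contrast-agent concentration on the dynamic time grid."""

    c_mM: np.ndarray  # (..., n_frames); NaN where the SPGR inversion failed
    times_min: np.ndarray
    relaxivity_r1: float
    baseline_frames: int
    valid_mask: np.ndarray | None = None  # voxels with a valid T1 fit


def spgr_signal(m0, t1_s, tr_ms, flip_deg):
    """Steady-state SPGR signal; broadcasts over array arguments."""
    m0 = np.asarray(m0, dtype=float)
    t1_s = np.asarray(t1_s, dtype=float)
    if np.any(t1_s <= 0):
        raise ValueError("t1_s must be > 0")
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("tr_ms must be > 0")
    flip = np.asarray(flip_deg, dtype=float)
    if np.any(flip <= 0) or np.any(flip > 90):
        raise ValueError("flip_deg must be in (0, 90]")
    a = np.deg2rad(flip)
    e1 = np.exp(-(np.asarray(tr_ms) / 1000.0) / t1_s)
    return m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


class VFAT1Mapper(BaseEstimator):
    """DESPOT1-style T1 estimation from variable-flip-angle SPGR signals.

    Parameters
    ----------
    flip_angles_deg : sequence of float
        Acquired flip angles (degrees), >= 2 distinct values.
    tr_ms : float
        Repetition time (ms).
    refine : bool, default True
        Polish the linearised estimate with a bounded nonlinear SPGR fit.

    Attributes
    ----------
    t1_s_, m0_ : ndarray, shape (n_voxels,)
    valid_mask_ : ndarray of bool
        False where the linearised slope falls outside (0, 1) — e.g. all-zero
        background voxels; such voxels carry NaN in ``t1_s_``.
    """

    def __init__(self, flip_angles_deg=(3, 5, 10, 15, 20, 30), tr_ms: float = 12.0, refine: bool = True):
        self.flip_angles_deg = flip_angles_deg
        self.tr_ms = tr_ms
        self.refine = refine

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        angles = np.asarray(self.flip_angles_deg, dtype=float)
        if X.shape[-1] != angles.size:
            raise ValueError("X last axis must match flip_angles_deg")
        tr_s = self.tr_ms / 1000.0
        a = np.deg2rad(angles)
        sin_a, tan_a = np.sin(a), np.tan(a)

        y_lin = X / sin_a  # (n, k)
        x_lin = X / tan_a
        xm = x_lin.mean(axis=1, keepdims=True)
        ym = y_lin.mean(axis=1, keepdims=True)
        sxx = ((x_lin - xm) ** 2).sum(axis=1)
        sxy = ((x_lin - xm) * (y_lin - ym)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = sxy / sxx
            intercept = ym[:, 0] - slope * xm[:, 0]
        valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & (intercept > 0)

        t1 = np.full(X.shape[0], np.nan)
        m0 = np.full(X.shape[0], np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            t1[valid] = -tr_s / np.log(slope[valid])
            m0[valid] = intercept[valid] / (1 - slope[valid])
        # noise-only voxels can linearize to absurd T1; flag, don't propagate
        valid &= np.nan_to_num(t1, nan=-1.0) > 1e-4
        valid &= np.nan_to_num(t1, nan=np.inf) < 20.0
        t1[~valid] = np.nan
        m0[~valid] = np.nan

        if self.refine:
            for i in np.flatnonzero(valid):
                sol = least_squares(
                    lambda th, s=X[i]: spgr_signal(th[0], th[1], self.tr_ms, angles) - s,
                    [max(m0[i], 1e-6), np.clip(t1[i], 2e-4, 19.9)],
                    bounds=([0, 1e-4], [np.inf, 20.0]),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
                m0[i], t1[i] = sol.x

        self.t1_s_ = t1
        self.m0_ = m0
        self.valid_mask_ = valid
        return self


def fit_vfa_t1(vfa: VFASeries, refine: bool = True) -> T1Map:
    """Fit T1/M0 per voxel from a VFA series of any spatial shape."""
    spatial = vfa.signal.shape[:-1]
    flat = vfa.signal.reshape(-1, vfa.signal.shape[-1])
    mapper = VFAT1Mapper(flip_angles_deg=vfa.flip_angles_deg, tr_ms=vfa.tr_ms, refine=refine).fit(flat)
    return T1Map(
        t1_s=mapper.t1_s_.reshape(spatial),
        m0=mapper.m0_.reshape(spatial),
        valid_mask=mapper.valid_mask_.reshape(spatial),
    )


def signal_to_concentration(
    dyn: DynamicSeries,
    t1map: T1Map,
    relaxivity_r1: float = DEFAULT_RELAXIVITY_R1,
    baseline_frames: int | None = None,
) -> ConcentrationSeries:
    """Convert dynamic SPGR signal to contrast concentration (mM).

    Per voxel: M0 is calibrated so the SPGR equation at the measured T10
    reproduces the baseline-average signal; each frame's signal is then
    inverted for T1(t) and C(t) = (1/T1(t) - 1/T10) / r1.  Frames whose
    signal falls outside the invertible range of the SPGR equation are NaN.
    Voxels without a valid T1 fit are skipped (NaN everywhere).
    """
    if relaxivity_r1 <= 0:
        raise ValueError("relaxivity_r1 must be > 0")
    nb = dyn.baseline_frames if baseline_frames is None else baseline_frames
    nf = dyn.signal.shape[-1]
    if not (1 <= nb < nf):
        raise ValueError("baseline_frames must be >= 1 and fewer than total frames")

    a = math.radians(dyn.flip_deg)
    sin_a, cos_a = math.sin(a), math.cos(a)
    tr_s = dyn.tr_ms / 1000.0

    c = np.full(dyn.signal.shape, np.nan)
    valid = np.asarray(t1map.valid_mask, dtype=bool)
    if valid.shape != dyn.signal.shape[:-1]:
        raise ValueError("t1map shape must match the spatial shape of the dynamic series")

    t10 = np.asarray(t1map.t1_s, dtype=float)[valid]  # (v,)
    s = dyn.signal[valid]  # (v, nf)
    s0 = s[:, :nb].mean(axis=1)
    e10 = np.exp(-tr_s / t10)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = s0 * (1 - e10 * cos_a) / (sin_a * (1 - e10))
        y = s / (m0 * sin_a)[:, None]
        e1 = (1 - y) / (1 - y * cos_a)
        invertible = (e1 > 0) & (e1 < 1) & np.isfinite(e1)
        r1t = np.where(invertible, -np.log(np.where(invertible, e1, 0.5)) / tr_s, np.nan)
        conc = (r1t - (1 / t10)[:, None]) / relaxivity_r1
    c[valid] = conc
    return ConcentrationSeries(
        c_mM=c,
        times_min=dyn.times_min,
        relaxivity_r1=relaxivity_r1,
        baseline_frames=nb,
        valid_mask=valid,
    )
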