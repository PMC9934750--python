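"""Digital DCE-MRI phantom: synthetic dynamic + VFA series with known truth.

The generator emulates a prostate dynamic contrast-enhanced study: a 3-D
grid of voxels grouped into labelled regions (cancer, normal zones, a
high-Ktrans "false positive" region, and a blood vessel for the AIF), each
governed by known tracer kinetics.  The forward chain is

    true kinetic params --> C(t)  (Tofts / 2TCM forward models)
    C(t)                --> R1(t) = 1/T10 + r1 C(t)
    R1(t)               --> SPGR signal at the dynamic TR/flip angle
                            (+ Gaussian or Rician noise)

plus a multi-flip-angle pre-contrast series from the same T10 map, so every
downstream stage (T1 mapping, concentration conversion, AIF extraction,
fitting, statistics) can be validated round-trip against exact ground truth.

Acquisition defaults follow a typical 3 T protocol: 60 dynamic frames at
8.3 s/frame, dynamic TR 4.6 ms at flip 10 deg, and a VFA series at
3/5/10/15/20/30 deg with TR 12 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaln

from .aif import AIF, DEFAULT_HCT
from .pkmodels import ToftsParams, TwoTCMParams, tofts_forward, twotcm_forward
from .relaxometry import (
    DEFAULT_RELAXIVITY_R1,
    DynamicSeries,
    VFASeries,
    spgr_signal,
)

__all__ = [
    "AIFShape",
    "RegionKinetics",
    "PhantomSpec",
    "PhantomOutput",
    "population_aif",
    "synthetic_aif",
    "default_spec",
    "build_phantom",
    "baseline_signal",
]


@dataclass(frozen=True)
class AIFShape:
    """Population bolus parameters: gamma-variate first pass + recirculation.

        Cp(t') = bolus_amp * GammaPDF(t'; alpha, beta)
                 + recirc_amp * (1 - exp(-t'/tau_on)) * exp(-t'/tau_off)

    with t' = t - arrival (zero before arrival).  GammaPDF is normalised to
    unit area, so ``bolus_amp`` is the first-pass area in mM*min.  Defaults
    give a plasma peak of about 5 mM roughly 27 s after bolus arrival with a
    slowly decaying ~0.6 mM tail.
    """

    arrival_min: float = 0.5
    alpha: float = 2.5
    beta: float = 0.18  # min
    bolus_amp: float = 3.7  # mM * min
    recirc_amp: float = 0.8  # mM
    tau_on: float = 0.3  # min
    tau_off: float = 6.0  # min


def population_aif(times_min, scale: float = 1.0, shape: AIFShape = AIFShape()) -> np.ndarray:
    """Parametric population plasma curve Cp(t) in mM.

    Cp(0) = 0, the curve is nonnegative, rises to a single dominant peak
    after the bolus arrival and decays toward a slowly washing-out plateau.
    """
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times_min must be a nonempty 1-D array")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times_min must be strictly increasing")
    tp = t - shape.arrival_min
    active = tp > 0
    tp = np.where(active, tp, 0.0)
    lognorm = (shape.alpha + 1) * np.log(shape.beta) + gammaln(shape.alpha + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bolus = np.where(
            active, np.exp(shape.alpha * np.log(np.where(active, tp, 1.0)) - tp / shape.beta - lognorm), 0.0
        )
    recirc = np.where(active, (1 - np.exp(-tp / shape.tau_on)) * np.exp(-tp / shape.tau_off), 0.0)
    return scale * (shape.bolus_amp * bolus + shape.recirc_amp * recirc)


def population_aif_integral(T_min: float, scale: float = 1.0, shape: AIFShape = AIFShape()) -> float:
    """Closed-form integral of :func:`population_aif` over [0, T] (mM*min)."""
    tp = T_min - shape.arrival_min
    if tp <= 0:
        return 0.0
    bolus = shape.bolus_amp * gammainc(shape.alpha + 1, tp / shape.beta)
    k = 1 / shape.tau_on + 1 / shape.tau_off
    recirc = shape.recirc_amp * (
        shape.tau_off * (1 - np.exp(-tp / shape.tau_off)) - (1 - np.exp(-k * tp)) / k
    )
    return float(scale * (bolus + recirc))


def synthetic_aif(times_min, scale: float = 1.0, shape: AIFShape = AIFShape(), hct: float = DEFAULT_HCT) -> AIF:
    """Population AIF wrapped as an :class:`~dce2tcm.aif.AIF` record."""
    cp = population_aif(times_min, scale=scale, shape=shape)
    return AIF(times_min=np.asarray(times_min, float), cp_mM=cp, cb_mM=cp * (1 - hct), hct=hct, source="synthetic")


@dataclass(frozen=True)
class RegionKinetics:
    """Ground-truth kinetics for one labelled region.

    model is "tofts" (params = ToftsParams), "2tcm" (params = TwoTCMParams,
    canonical amplitude-ordered), or "blood" (params = None; the region
    carries whole-blood concentration Cb = (1 - Hct) * Cp for AIF tracing).
    """

    name: str
    model: str
    params: "ToftsParams | TwoTCMParams | None"
    t10_s: float
    m0: float = 1000.0

    def __post_init__(self):
        if self.model not in ("tofts", "2tcm", "blood"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.t10_s <= 0:
            raise ValueError("t10_s must be > 0")


@dataclass
class PhantomSpec:
    """Full description of a synthetic study; identical spec + seed give
    bit-identical output."""

    grid_shape: tuple = (32, 32, 3)
    regions: dict = field(default_factory=dict)  # label (int >= 1) -> RegionKinetics
    region_map: np.ndarray | None = None  # int labels, 0 = background; None -> default block layout
    roi_slices: tuple = (0, 1)
    n_frames: int = 60
    frame_interval_s: float = 8.3
    tr_ms: float = 4.6
    flip_deg: float = 10.0
    vfa_angles_deg: tuple = (3, 5, 10, 15, 20, 30)
    vfa_tr_ms: float = 12.0
    relaxivity_r1: float = DEFAULT_RELAXIVITY_R1
    hct: float = DEFAULT_HCT
    aif_shape: AIFShape = field(default_factory=AIFShape)
    noise_sd: float = 0.0  # absolute, signal units
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not (0 <= self.hct < 1):
            raise ValueError("hct must be in [0, 1)")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0


@dataclass
class PhantomOutput:
    dynamic: DynamicSeries
    vfa: VFASeries
    roi_masks: dict  # region name -> boolean mask
    ground_truth: pd.DataFrame  # one row per non-background voxel
    true_aif: AIF
    t10_map: np.ndarray
    region_map: np.ndarray
    spec: PhantomSpec


def _default_regions() -> dict:
    """The default tissue scenario (generator truth, not clinical claims):

    cancer has a strong fast plus a slow compartment; normal zones are lower
    throughout; the false-positive region has a cancer-like total Ktrans but
    a low fast-compartment amplitude (dominant slow exchange), so Tofts
    flags it while the 2TCM fast amplitude does not; blood carries the AIF.
    """
    return {
        1: RegionKinetics("cancer", "2tcm", TwoTCMParams(0.25, 1.2, 0.05, 0.2), t10_s=1.6),
        2: RegionKinetics("normal_pz", "2tcm", TwoTCMParams(0.10, 0.45, 0.02, 0.10), t10_s=1.4),
        3: RegionKinetics("normal_tz", "tofts", ToftsParams(0.05, 0.30), t10_s=1.4),
        4: RegionKinetics("false_positive", "2tcm", TwoTCMParams(0.20, 0.25, 0.10, 0.90), t10_s=1.5),
        5: RegionKinetics("blood", "blood", None, t10_s=1.9, m0=1200.0),
    }


def _default_region_map(grid_shape, roi_slices, labels) -> np.ndarray:
    """Square blocks per region on each ROI slice; other slices stay empty."""
    region_map = np.zeros(grid_shape, dtype=np.int16)
    nr, nc, _ = grid_shape
    blocks = {
        1: (slice(4, 10), slice(4, 10)),
        2: (slice(4, 10), slice(14, 20)),
        3: (slice(14, 20), slice(4, 10)),
        4: (slice(14, 20), slice(14, 20)),
        5: (slice(26, 30), slice(26, 30)),
    }
    scale_r, scale_c = nr / 32.0, nc / 32.0

    def rescale(sl, s, n):
        lo, hi = int(round(sl.start * s)), int(round(sl.stop * s))
        return slice(min(lo, n - 2), max(min(hi, n), min(lo, n - 2) + 1))

    for label in labels:
        rs, cs = blocks[label]
        for z in roi_slices:
            region_map[rescale(rs, scale_r, nr), rescale(cs, scale_c, nc), z] = label
    return region_map


def default_spec(**overrides) -> PhantomSpec:
    """The standard phantom scenario used throughout the test battery."""
    kw = dict(regions=_default_regions())
    kw.update(overrides)
    return PhantomSpec(**kw)


def baseline_signal(spec: PhantomSpec, label: int = 2) -> float:
    """Noiseless pre-contrast dynamic signal of one region (for noise scaling)."""
    reg = spec.regions[label]
    return float(spgr_signal(reg.m0, reg.t10_s, spec.tr_ms, spec.flip_deg))


def _region_concentration(reg: RegionKinetics, aif: AIF, hct: float) -> np.ndarray:
    if reg.model == "tofts":
        return tofts_forward(reg.params, aif)
    if reg.model == "2tcm":
        return twotcm_forward(reg.params, aif)
    return aif.cp_mM * (1 - hct)  # blood: whole-blood concentration


def _add_noise(signal: np.ndarray, sd: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sd, signal.shape)
    # rician: magnitude of complex signal with iid Gaussian noise per channel
    re = signal + rng.normal(0.0, sd, signal.shape)
    im = rng.normal(0.0, sd, signal.shape)
    return np.hypot(re, im)


def build_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Synthesize the full study: dynamic series, VFA series, masks, truth."""
    if spec.region_map is None:
        region_map = _default_region_map(spec.grid_shape, spec.roi_slices, spec.regions.keys())
    else:
        region_map = np.asarray(spec.region_map)
        if region_map.shape != tuple(spec.grid_shape):
            raise ValueError("region_map shape must equal grid_shape")
    labels = np.unique(region_map)
    labels = labels[labels > 0]
    missing = [int(l) for l in labels if int(l) not in spec.regions]
    if missing:
        raise ValueError(f"region_map labels without kinetics: {missing}")

    times_min = spec.times_min
    true_aif = synthetic_aif(times_min, shape=spec.aif_shape, hct=spec.hct)

    shape4 = tuple(spec.grid_shape) + (spec.n_frames,)
    dyn_signal = np.zeros(shape4)
    t10_map = np.zeros(spec.grid_shape)
    m0_map = np.zeros(spec.grid_shape)
    rows = []
    for label in labels:
        reg = spec.regions[int(label)]
        mask = region_map == label
        conc = _region_concentration(reg, true_aif, spec.hct)
        r1t = 1.0 / reg.t10_s + spec.relaxivity_r1 * conc  # s^-1
        sig = spgr_signal(reg.m0, 1.0 / r1t, spec.tr_ms, spec.flip_deg)
        dyn_signal[mask] = sig
        t10_map[mask] = reg.t10_s
        m0_map[mask] = reg.m0
        for (r, c, z) in np.argwhere(mask):
            row = {
                "row": r, "col": c, "slice": z,
                "label": int(label), "region": reg.name, "model": reg.model,
                "t10_s": reg.t10_s,
            }
            if reg.model == "tofts":
                row.update(ktrans=reg.params.ktrans, kep=reg.params.kep)
            elif reg.model == "2tcm":
                row.update(
                    k1trans=reg.params.k1trans, kep1=reg.params.kep1,
                    k2trans=reg.params.k2trans, kep2=reg.params.kep2,
                )
            rows.append(row)
    ground_truth = pd.DataFrame(rows)

    vfa_clean = np.zeros(tuple(spec.grid_shape) + (len(spec.vfa_angles_deg),))
    tissue = region_map > 0
    if np.any(tissue):
        vfa_clean[tissue] = spgr_signal(
            m0_map[tissue][:, None],
            t10_map[tissue][:, None],
            spec.vfa_tr_ms,
            np.asarray(spec.vfa_angles_deg, float)[None, :],
        )

    rng = np.random.default_rng(spec.seed)
    dyn_signal = _add_noise(dyn_signal, spec.noise_sd, spec.noise_model, rng)
    vfa_signal = _add_noise(vfa_clean, spec.noise_sd, spec.noise_model, rng)

    dynamic = DynamicSeries(
        signal=dyn_signal, times_min=times_min, tr_ms=spec.tr_ms, flip_deg=spec.flip_deg,
        baseline_frames=max(1, int(np.searchsorted(times_min, spec.aif_shape.arrival_min))),
    )
    vfa = VFASeries(signal=vfa_signal, flip_angles_deg=np.asarray(spec.vfa_angles_deg, float), tr_ms=spec.vfa_tr_ms)
    roi_masks = {spec.regions[int(l)].name: region_map == l for l in labels}
    return PhantomOutput(
        dynamic=dynamic, vfa=vfa, roi_masks=roi_masks, ground_truth=ground_truth,
        true_aif=true_aif, t10_map=t10_map, region_map=region_map, spec=spec,
    )
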