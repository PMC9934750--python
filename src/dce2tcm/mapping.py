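"""Voxelwise map generation, ROI summaries, and the false-positive-ROI rule.

Parametric maps are generated only for the slices carrying ROIs.  Unfitted
voxels hold NaN (never zero, which would be a legal rate).  The
"false positive" selection mimics the reading-room situation where a benign
region lights up on the Ktrans map: given a traced candidate region and a
nearby cancer ROI, voxels are kept when their Ktrans reaches the cancer
ROI's mean minus a multiple (default 1) of its standard deviation, so the
selected ROI has an average Ktrans close to the cancer average.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .aif import AIF
from .pkmodels import fit_2tcm, fit_tofts
from .relaxometry import ConcentrationSeries

log = logging.getLogger(__name__)

__all__ = [
    "ParametricMaps",
    "ROIRecord",
    "fit_volume",
    "roi_mean",
    "select_false_positive_roi",
    "TOFTS_MAP_NAMES",
    "TWOTCM_MAP_NAMES",
]

TOFTS_MAP_NAMES = ("ktrans", "kep", "ve", "rmse")
TWOTCM_MAP_NAMES = ("k1trans", "kep1", "k2trans", "kep2", "ve1", "ve2", "rmse")


@dataclass
class ParametricMaps:
    """One 3-D array per parameter plus fit bookkeeping; NaN = unfitted."""

    model: str
    maps: dict  # name -> 3-D float array
    fitted_mask: np.ndarray
    converged: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


@dataclass
class ROIRecord:
    """A labelled voxel set with its per-parameter means."""

    label: str
    voxels: np.ndarray  # (n, 3) int indices
    means: dict = field(default_factory=dict)


def _as_voxels(roi) -> np.ndarray:
    roi = np.asarray(roi)
    if roi.dtype == bool:
        return np.argwhere(roi)
    if roi.ndim != 2 or roi.shape[1] != 3:
        raise ValueError("ROI must be a boolean mask or an (n, 3) index array")
    return roi.astype(int)


def fit_volume(
    conc: ConcentrationSeries,
    aif: AIF,
    slices,
    model: str,
    mask: np.ndarray | None = None,
    seed: int = 0,
    n_jitter: int = 3,
) -> ParametricMaps:
    """Fit every eligible voxel on the listed slices and assemble maps.

    Eligible = inside ``mask`` (default: all voxels with a valid T1 fit),
    on a listed slice, with an all-finite concentration curve.  Multistart
    jitter for the 2TCM is seeded per voxel from its linear index, so the
    result is independent of visiting order and reproducible for a given
    ``seed``.
    """
    if model not in ("tofts", "2tcm"):
        raise ValueError(f"unknown model {model!r}")
    slices = np.atleast_1d(np.asarray(slices, dtype=int))
    if slices.size == 0:
        raise ValueError("slices must be nonempty")
    shape = conc.c_mM.shape[:-1]
    if mask is None:
        mask = conc.valid_mask if conc.valid_mask is not None else np.ones(shape, bool)
    mask = np.asarray(mask, dtype=bool)

    slice_sel = np.zeros(shape, dtype=bool)
    slice_sel[:, :, slices] = True
    finite = np.all(np.isfinite(conc.c_mM), axis=-1)
    eligible = mask & slice_sel & finite

    names = TOFTS_MAP_NAMES if model == "tofts" else TWOTCM_MAP_NAMES
    maps = {name: np.full(shape, np.nan) for name in names}
    fitted = np.zeros(shape, dtype=bool)
    converged = np.zeros(shape, dtype=bool)
    voxels = np.argwhere(eligible)
    if voxels.shape[0] == 0:
        log.warning("fit_volume: no eligible voxels on slices %s", slices.tolist())
        return ParametricMaps(model, maps, fitted, converged)

    for (r, c, z) in voxels:
        curve = conc.c_mM[r, c, z, :]
        idx = (r, c, z)
        if model == "tofts":
            res = fit_tofts(curve, aif)
            p = res.params
            maps["ktrans"][idx], maps["kep"][idx], maps["ve"][idx] = p.ktrans, p.kep, p.ve
        else:
            lin = int(np.ravel_multi_index(idx, shape))
            res = fit_2tcm(curve, aif, n_jitter=n_jitter, seed=(seed + lin) % 2**31)
            p = res.params
            maps["k1trans"][idx], maps["kep1"][idx] = p.k1trans, p.kep1
            maps["k2trans"][idx], maps["kep2"][idx] = p.k2trans, p.kep2
            maps["ve1"][idx], maps["ve2"][idx] = p.ve1, p.ve2
        maps["rmse"][idx] = res.rmse
        fitted[idx] = True
        converged[idx] = res.converged
    return ParametricMaps(model, maps, fitted, converged)


def roi_mean(maps: ParametricMaps, roi) -> dict:
    """Arithmetic mean of every parameter over the ROI's fitted voxels."""
    vox = _as_voxels(roi.voxels if isinstance(roi, ROIRecord) else roi)
    if vox.shape[0] == 0:
        raise ValueError("ROI is empty")
    inside = maps.fitted_mask[tuple(vox.T)]
    if not np.any(inside):
        raise ValueError("ROI lies entirely outside the fitted mask")
    vox = vox[inside]
    return {name: float(np.nanmean(arr[tuple(vox.T)])) for name, arr in maps.maps.items()}


def select_false_positive_roi(
    ktrans_map: np.ndarray,
    cancer_roi,
    candidate_region,
    sd_multiplier: float = 1.0,
    label: str = "false_positive",
) -> ROIRecord:
    """Select the 'false positive' ROI by the cancer-referenced cutoff.

    cutoff = mean(Ktrans over cancer ROI) - sd_multiplier * SD (sample SD,
    n-1 denominator); candidate voxels with Ktrans >= cutoff are kept
    (boundary included).  Enlarging the candidate set never removes
    previously selected voxels.  Returns an empty ROI (with a warning) when
    nothing passes.
    """
    cancer = _as_voxels(cancer_roi)
    cand = _as_voxels(candidate_region)
    if cancer.shape[0] < 2:
        raise ValueError("cancer ROI needs >= 2 voxels to define an SD")
    if cand.shape[0] == 0:
        raise ValueError("candidate region must be nonempty")
    cancer_set = set(map(tuple, cancer))
    if any(tuple(v) in cancer_set for v in cand):
        raise ValueError("candidate region must be disjoint from the cancer ROI")

    kt = np.asarray(ktrans_map, dtype=float)
    cvals = kt[tuple(cancer.T)]
    cutoff = float(np.mean(cvals) - sd_multiplier * np.std(cvals, ddof=1))
    cand_vals = kt[tuple(cand.T)]
    keep = cand_vals >= cutoff
    selected = cand[keep]
    if selected.shape[0] == 0:
        warnings.warn("no candidate voxel reaches the false-positive cutoff; empty ROI")
        return ROIRecord(label, selected, {"ktrans": float("nan"), "cutoff": cutoff})
    return ROIRecord(label, selected, {"ktrans": float(np.mean(cand_vals[keep])), "cutoff": cutoff})
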