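"""Arterial input function: plasma concentration derived from a blood ROI.

The kinetic models are driven by the plasma concentration Cp(t).  What a
blood-vessel ROI measures is the whole-blood concentration Cb(t); the two
are related through the hematocrit Hct (the volume fraction of blood
occupied by cells, which excludes tracer):

    Cp(t) = Cb(t) / (1 - Hct)

with Hct = 0.42 as the population default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_HCT = 0.42

__all__ = ["AIF", "extract_aif", "DEFAULT_HCT"]


@dataclass
class AIF:
    """Plasma input function on the dynamic time grid.

    Attributes
    ----------
    times_min : ndarray
        Frame times in minutes, t = 0 at the first dynamic frame.
    cp_mM : ndarray
        Plasma concentration per frame (mM).
    cb_mM : ndarray or None
        Whole-blood concentration per frame, when derived from a blood ROI.
    hct : float
        Hematocrit fraction used for the plasma conversion.
    source : str
        ROI identifier, or "synthetic" for a population curve.
    """

    times_min: np.ndarray
    cp_mM: np.ndarray
    cb_mM: np.ndarray | None = None
    hct: float = DEFAULT_HCT
    source: str = "synthetic"

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.cp_mM = np.asarray(self.cp_mM, dtype=float)
        if self.cb_mM is not None:
            self.cb_mM = np.asarray(self.cb_mM, dtype=float)
        if self.times_min.shape != self.cp_mM.shape:
            raise ValueError("times_min and cp_mM must have the same shape")
        if not (0 <= self.hct < 1):
            raise ValueError(f"hct must be in [0, 1), got {self.hct}")
        if not np.all(np.isfinite(self.cp_mM)):
            raise ValueError("cp_mM must be finite")


def extract_aif(conc, blood_roi, hct: float = DEFAULT_HCT, source: str = "blood_roi") -> AIF:
    """Derive the AIF from a blood-vessel ROI on a concentration series.

    Parameters
    ----------
    conc : ConcentrationSeries
        Voxelwise concentration with spatial leading axes and frames last.
    blood_roi : boolean mask or (n, 3) integer voxel index array
        Voxels of the traced vessel ROI; aggregated by unweighted mean.
    hct : float
        Hematocrit in [0, 1); cp = cb / (1 - hct).
    """
    if not (0 <= hct < 1):
        raise ValueError(f"hct must be in [0, 1), got {hct}")
    c = np.asarray(conc.c_mM, dtype=float)
    roi = np.asarray(blood_roi)
    if roi.dtype == bool:
        curves = c[roi]
    else:
        if roi.ndim != 2 or roi.shape[0] == 0:
            raise ValueError("blood_roi must be nonempty")
        curves = c[tuple(roi.T)]
    if curves.size == 0:
        raise ValueError("blood_roi must be nonempty")
    if not np.all(np.isfinite(curves)):
        raise ValueError("blood ROI contains invalid (non-finite) concentration voxels")
    cb = curves.mean(axis=0)
    return AIF(
        times_min=np.asarray(conc.times_min, dtype=float),
        cp_mM=cb / (1.0 - hct),
        cb_mM=cb,
        hct=hct,
        source=source,
    )
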