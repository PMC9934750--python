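"""Reading and writing of NIfTI volumes, ROI tables, AIF curves and specs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .aif import AIF
from .phantom import AIFShape, PhantomSpec, RegionKinetics
from .pkmodels import ToftsParams, TwoTCMParams

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_aif_csv",
    "load_aif_csv",
    "load_roi",
    "spec_to_yaml",
    "spec_from_yaml",
]


def save_nifti(array: np.ndarray, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_aif_csv(aif: AIF, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_min": aif.times_min, "cp_mM": aif.cp_mM}).to_csv(path, index=False)
    return path


def load_aif_csv(path, hct: float | None = None) -> AIF:
    df = pd.read_csv(path)
    kw = {} if hct is None else {"hct": hct}
    return AIF(times_min=df["time_min"].to_numpy(), cp_mM=df["cp_mM"].to_numpy(), source=str(path), **kw)


def load_roi(path) -> np.ndarray:
    """Load an ROI as a boolean mask (NIfTI labels != 0) or as an (n, 3)
    voxel index array (CSV with row, col, slice columns)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        return df[["row", "col", "slice"]].to_numpy(dtype=int)
    return load_nifti(path) != 0


def _params_to_dict(reg: RegionKinetics) -> dict:
    d = {"name": reg.name, "model": reg.model, "t10_s": reg.t10_s, "m0": reg.m0}
    if reg.model == "tofts":
        d["params"] = {"ktrans": reg.params.ktrans, "kep": reg.params.kep}
    elif reg.model == "2tcm":
        d["params"] = {
            "k1trans": reg.params.k1trans, "kep1": reg.params.kep1,
            "k2trans": reg.params.k2trans, "kep2": reg.params.kep2,
        }
    return d


def spec_to_yaml(spec: PhantomSpec, path) -> Path:
    d = {
        "grid_shape": list(spec.grid_shape),
        "roi_slices": list(spec.roi_slices),
        "n_frames": spec.n_frames,
        "frame_interval_s": spec.frame_interval_s,
        "tr_ms": spec.tr_ms,
        "flip_deg": spec.flip_deg,
        "vfa_angles_deg": list(spec.vfa_angles_deg),
        "vfa_tr_ms": spec.vfa_tr_ms,
        "relaxivity_r1": spec.relaxivity_r1,
        "hct": spec.hct,
        "aif_shape": asdict(spec.aif_shape),
        "noise_sd": spec.noise_sd,
        "noise_model": spec.noise_model,
        "seed": spec.seed,
        "regions": {int(k): _params_to_dict(v) for k, v in spec.regions.items()},
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def spec_from_yaml(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    regions = {}
    for label, rd in d.pop("regions", {}).items():
        model = rd["model"]
        if model == "tofts":
            params = ToftsParams(**rd["params"])
        elif model == "2tcm":
            params = TwoTCMParams(**rd["params"])
        else:
            params = None
        regions[int(label)] = RegionKinetics(
            name=rd["name"], model=model, params=params, t10_s=rd["t10_s"], m0=rd.get("m0", 1000.0)
        )
    d["regions"] = regions
    d["grid_shape"] = tuple(d["grid_shape"])
    d["roi_slices"] = tuple(d["roi_slices"])
    d["vfa_angles_deg"] = tuple(d["vfa_angles_deg"])
    d["aif_shape"] = AIFShape(**d["aif_shape"])
    return PhantomSpec(**d)
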