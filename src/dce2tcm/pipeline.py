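"""End-to-end orchestration: phantom or measured data through maps and stats.

Stage order: simulate (optional) -> VFA T1 map -> concentration -> AIF ->
per-voxel fits (Tofts, 2TCM) -> parametric maps -> ROI summaries and the
false-positive ROI -> statistics.  A manifest (config + seed + versions) is
written alongside the outputs; rerunning from the same manifest regenerates
every table identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aif import extract_aif
from .io import (
    load_aif_csv,
    load_nifti,
    load_roi,
    save_aif_csv,
    save_nifti,
    spec_from_yaml,
    spec_to_yaml,
)
from .mapping import fit_volume, roi_mean, select_false_positive_roi
from .phantom import PhantomSpec, build_phantom
from .relaxometry import DynamicSeries, VFASeries, fit_vfa_t1, signal_to_concentration
from .stats import anova_tukey, logistic_combine, paired_ttest, pearson_r, roc_auc

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigurationError", "run_pipeline", "run_from_manifest"]


class ConfigurationError(ValueError):
    """Raised for invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a run needs; phantom mode synthesizes its own inputs."""

    phantom: PhantomSpec | None = None
    dynamic_path: str | None = None
    vfa_path: str | None = None
    blood_roi_path: str | None = None
    aif_csv_path: str | None = None
    roi_paths: dict = field(default_factory=dict)  # name -> mask path
    roi_slices: tuple | None = None
    frame_interval_s: float = 8.3
    tr_ms: float = 4.6
    flip_deg: float = 10.0
    vfa_angles_deg: tuple = (3, 5, 10, 15, 20, 30)
    vfa_tr_ms: float = 12.0
    relaxivity_r1: float = 5.5
    hct: float = 0.42
    baseline_frames: int = 4
    models: tuple = ("tofts", "2tcm")
    sd_multiplier: float = 1.0
    cancer_roi: str = "cancer"
    false_positive_candidate_roi: str = "false_positive"
    seed: int = 0

    def validate(self):
        if not (0 <= self.hct < 1):
            raise ConfigurationError(f"hct must be in [0, 1), got {self.hct}")
        for m in self.models:
            if m not in ("tofts", "2tcm"):
                raise ConfigurationError(f"unknown model {m!r}")
        if self.phantom is None:
            for label, p in [("dynamic series", self.dynamic_path), ("VFA series", self.vfa_path)]:
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"missing {label} input: {p}")
            if self.aif_csv_path is None and self.blood_roi_path is None:
                raise ConfigurationError("missing AIF input: provide aif_csv_path or blood_roi_path")
            for label, p in [("AIF CSV", self.aif_csv_path), ("blood ROI", self.blood_roi_path)]:
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"missing {label} input: {p}")
            for name, p in self.roi_paths.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"missing ROI mask input ({name}): {p}")


def _versions() -> dict:
    import nibabel, scipy, sklearn, statsmodels

    return {
        "dce2tcm": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }


def _maps_to_frame(maps, model: str) -> pd.DataFrame:
    vox = np.argwhere(maps.fitted_mask)
    rows = {"row": vox[:, 0], "col": vox[:, 1], "slice": vox[:, 2]}
    for name, arr in maps.maps.items():
        rows[f"{model}_{name}"] = arr[tuple(vox.T)]
    rows[f"{model}_converged"] = maps.converged[tuple(vox.T)]
    return pd.DataFrame(rows)


def _safe(fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except ValueError as e:
        log.warning("statistic undefined: %s", e)
        return None


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages and write NIfTI/CSV/JSON outputs under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs: simulate or load -------------------------------------
    if config.phantom is not None:
        ph = build_phantom(config.phantom)
        dyn, vfa = ph.dynamic, ph.vfa
        roi_masks = {k: v for k, v in ph.roi_masks.items() if k != "blood"}
        blood_mask = ph.roi_masks.get("blood")
        roi_slices = tuple(config.phantom.roi_slices)
        spec_to_yaml(config.phantom, out / "phantom_spec.yaml")
        ph.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        save_nifti(dyn.signal, out / "dynamic.nii")
        save_nifti(vfa.signal, out / "vfa.nii")
        save_nifti(ph.region_map.astype(float), out / "region_map.nii")
        hct = config.phantom.hct
        r1 = config.phantom.relaxivity_r1
        truth = ph.ground_truth
    else:
        times_min = None
        sig = load_nifti(config.dynamic_path)
        times_min = np.arange(sig.shape[-1]) * config.frame_interval_s / 60.0
        dyn = DynamicSeries(
            signal=sig, times_min=times_min, tr_ms=config.tr_ms,
            flip_deg=config.flip_deg, baseline_frames=config.baseline_frames,
        )
        vfa = VFASeries(
            signal=load_nifti(config.vfa_path),
            flip_angles_deg=np.asarray(config.vfa_angles_deg, float),
            tr_ms=config.vfa_tr_ms,
        )
        roi_masks = {name: load_roi(p) for name, p in config.roi_paths.items()}
        blood_mask = load_roi(config.blood_roi_path) if config.blood_roi_path else None
        roi_slices = config.roi_slices
        if roi_slices is None:
            union = np.zeros(sig.shape[:-1], bool)
            for m in roi_masks.values():
                union |= np.asarray(m, bool)
            roi_slices = tuple(np.unique(np.argwhere(union)[:, 2]).tolist()) or (0,)
        hct, r1, truth = config.hct, config.relaxivity_r1, None

    # ---- T1 map and concentration -------------------------------------
    t1map = fit_vfa_t1(vfa)
    save_nifti(np.where(t1map.valid_mask, t1map.t1_s, np.nan), out / "t1_map.nii")
    conc = signal_to_concentration(dyn, t1map, relaxivity_r1=r1, baseline_frames=config.baseline_frames
                                   if config.phantom is None else dyn.baseline_frames)
    save_nifti(conc.c_mM, out / "concentration.nii")

    # ---- AIF -----------------------------------------------------------
    if config.phantom is None and config.aif_csv_path is not None:
        aif = load_aif_csv(config.aif_csv_path, hct=hct)
    else:
        finite = np.all(np.isfinite(conc.c_mM), axis=-1)
        blood_vox = np.argwhere(np.asarray(blood_mask, bool) & conc.valid_mask & finite)
        if blood_vox.shape[0] == 0:
            raise ConfigurationError("blood ROI contains no valid voxels for AIF extraction")
        aif = extract_aif(conc, blood_vox, hct=hct)
    save_aif_csv(aif, out / "aif.csv")

    # ---- per-voxel fits and maps ---------------------------------------
    tissue_mask = np.zeros(conc.c_mM.shape[:-1], bool)
    for m in roi_masks.values():
        mask = np.asarray(m)
        if mask.dtype != bool:
            vox = mask.astype(int)
            mask = np.zeros(tissue_mask.shape, bool)
            mask[tuple(vox.T)] = True
        tissue_mask |= mask
    fits = {}
    frames = []
    for model in config.models:
        maps = fit_volume(conc, aif, roi_slices, model, mask=tissue_mask, seed=config.seed)
        fits[model] = maps
        for name, arr in maps.maps.items():
            save_nifti(arr, out / f"map_{model}_{name}.nii")
        frames.append(_maps_to_frame(maps, model))
    voxel_df = frames[0]
    for f in frames[1:]:
        voxel_df = voxel_df.merge(f, on=["row", "col", "slice"], how="outer")
    voxel_df = voxel_df.sort_values(["slice", "row", "col"]).reset_index(drop=True)
    voxel_df.to_csv(out / "voxel_fits.csv", index=False)

    # ---- ROI summaries and false-positive rule -------------------------
    roi_rows = []
    for name, m in roi_masks.items():
        vox = np.argwhere(np.asarray(m, bool)) if np.asarray(m).dtype == bool else np.asarray(m, int)
        for model, maps in fits.items():
            means = _safe(roi_mean, maps, vox)
            if means is None:
                continue
            row = {"roi": name, "model": model, "n_voxels": int(vox.shape[0])}
            row.update({k: v for k, v in means.items()})
            roi_rows.append(row)
    pd.DataFrame(roi_rows).to_csv(out / "roi_summary.csv", index=False)

    fp_row = None
    if "tofts" in fits and config.cancer_roi in roi_masks and config.false_positive_candidate_roi in roi_masks:
        ktrans_map = fits["tofts"]["ktrans"]
        cancer_vox = np.argwhere(np.asarray(roi_masks[config.cancer_roi], bool))
        cand_vox = np.argwhere(np.asarray(roi_masks[config.false_positive_candidate_roi], bool))
        cancer_vox = cancer_vox[np.isfinite(ktrans_map[tuple(cancer_vox.T)])]
        cand_vox = cand_vox[np.isfinite(ktrans_map[tuple(cand_vox.T)])]
        if cancer_vox.shape[0] >= 2 and cand_vox.shape[0] > 0:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fp = select_false_positive_roi(
                    ktrans_map, cancer_vox, cand_vox, sd_multiplier=config.sd_multiplier
                )
            pd.DataFrame(fp.voxels, columns=["row", "col", "slice"]).to_csv(
                out / "false_positive_roi.csv", index=False
            )
            fp_row = {
                "cutoff": fp.means["cutoff"],
                "n_selected": int(fp.voxels.shape[0]),
                "mean_ktrans": fp.means["ktrans"],
            }

    # ---- statistics -----------------------------------------------------
    report = {"false_positive_roi": fp_row}
    stats_report, tables = compute_statistics(
        fits, roi_masks, cancer_roi=config.cancer_roi, fp_roi=config.false_positive_candidate_roi
    )
    report.update(stats_report)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    # phantom mode: parameter-recovery summary against ground truth
    if truth is not None:
        rec_rows = []
        for (region, model), sub in truth.groupby(["region", "model"]):
            if model not in fits:
                continue
            maps = fits[model]
            vox = sub[["row", "col", "slice"]].to_numpy()
            fitted = maps.fitted_mask[tuple(vox.T)]
            if not fitted.any():
                continue
            vox = vox[fitted]
            pnames = ("ktrans", "kep") if model == "tofts" else ("k1trans", "kep1", "k2trans", "kep2")
            for pn in pnames:
                true_val = float(sub[pn].iloc[0])
                est = maps[pn][tuple(vox.T)]
                rec_rows.append(
                    {"region": region, "model": model, "parameter": pn, "true": true_val,
                     "mean_estimate": float(np.mean(est)),
                     "max_rel_error_pct": float(100 * np.max(np.abs(est - true_val)) / true_val)
                     if true_val > 0 else None}
                )
        pd.DataFrame(rec_rows).to_csv(out / "recovery.csv", index=False)
        report["recovery"] = rec_rows

    (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))

    manifest = {
        "seed": config.seed,
        "models": list(config.models),
        "relaxivity_r1": r1,
        "hct": hct,
        "sd_multiplier": config.sd_multiplier,
        "phantom_spec": "phantom_spec.yaml" if config.phantom is not None else None,
        "inputs": {
            "dynamic": config.dynamic_path, "vfa": config.vfa_path,
            "blood_roi": config.blood_roi_path, "aif_csv": config.aif_csv_path,
            "rois": dict(config.roi_paths),
        },
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def compute_statistics(fits: dict, roi_masks: dict, cancer_roi: str = "cancer", fp_roi: str = "false_positive"):
    """Model-comparison and discrimination statistics from fitted maps.

    Returns ``(report, tables)`` where ``report`` is a JSON-ready dict and
    ``tables`` maps CSV stem -> DataFrame.  Statistics that are undefined on
    the given data (e.g. zero-variance groups on a noiseless phantom) are
    recorded as None rather than raising.
    """
    report: dict = {}
    tables: dict = {}
    if "tofts" in fits and "2tcm" in fits:
        both = fits["tofts"].fitted_mask & fits["2tcm"].fitted_mask
        r_t = fits["tofts"]["rmse"][both]
        r_2 = fits["2tcm"]["rmse"][both]
        tt = _safe(paired_ttest, r_t, r_2)
        report["rmse_comparison"] = {
            "n_voxels": int(both.sum()),
            "rmse_tofts_mean": float(r_t.mean()) if r_t.size else None,
            "rmse_tofts_sd": float(r_t.std(ddof=1)) if r_t.size > 1 else None,
            "rmse_2tcm_mean": float(r_2.mean()) if r_2.size else None,
            "rmse_2tcm_sd": float(r_2.std(ddof=1)) if r_2.size > 1 else None,
            "paired_t": tt[0] if tt else None,
            "paired_t_p": tt[2] if tt else None,
            "nesting_fraction": float(np.mean(r_2 <= r_t + 1e-9)) if r_t.size else None,
        }

        # correlations between corresponding Tofts and 2TCM parameters
        cancer_mask = np.asarray(roi_masks.get(cancer_roi, np.zeros_like(both)), bool)
        normal_masks = [
            np.asarray(m, bool)
            for name, m in roi_masks.items()
            if name not in (cancer_roi, fp_roi)
        ]
        normal_mask = np.any(normal_masks, axis=0) if normal_masks else np.zeros_like(both)
        corr_rows = []
        for tissue, tmask in [("cancer", cancer_mask), ("normal", normal_mask)]:
            sel = both & tmask
            for a, b in [("ktrans", "k1trans"), ("ktrans", "k2trans"), ("kep", "kep1"), ("kep", "kep2")]:
                rp = _safe(pearson_r, fits["tofts"][a][sel], fits["2tcm"][b][sel])
                corr_rows.append(
                    {"tissue": tissue, "tofts_param": a, "twotcm_param": b,
                     "n": int(sel.sum()),
                     "r": rp[0] if rp else None, "p": rp[1] if rp else None}
                )
        tables["correlations"] = pd.DataFrame(corr_rows)
        report["correlations"] = corr_rows

    # group comparison + ROC/logistic per model (cancer vs pooled normal)
    cancer_mask = np.asarray(roi_masks[cancer_roi], bool) if cancer_roi in roi_masks else None
    if cancer_mask is not None:
        fp_name = fp_roi
        normal_masks = [np.asarray(m, bool) for n, m in roi_masks.items() if n not in (cancer_roi, fp_name)]
        normal_mask = np.any(normal_masks, axis=0) if normal_masks else None
        fp_mask = np.asarray(roi_masks[fp_name], bool) if fp_name in roi_masks else None
        roc_rows, group_rows = [], []
        for model, maps in fits.items():
            pnames = [n for n in maps.maps if n not in ("rmse",)]
            feats_pos, feats_neg = [], []
            for pn in pnames:
                arr = maps[pn]
                pos = arr[cancer_mask & maps.fitted_mask]
                neg = arr[normal_mask & maps.fitted_mask] if normal_mask is not None else np.array([])
                if pn in ("ktrans", "kep", "k1trans", "kep1", "k2trans", "kep2"):
                    feats_pos.append(pos)
                    feats_neg.append(neg)
                rr = _safe(roc_auc, pos, neg) if neg.size else None
                roc_rows.append(
                    {"model": model, "parameter": pn,
                     "auc": rr.auc if rr else None,
                     "ci95_low": rr.ci95_low if rr else None,
                     "ci95_high": rr.ci95_high if rr else None}
                )
                groups = {"cancer": pos}
                if normal_mask is not None:
                    groups["normal"] = neg
                if fp_mask is not None:
                    groups["false_positive"] = arr[fp_mask & maps.fitted_mask]
                gc = _safe(anova_tukey, {k: v for k, v in groups.items() if np.asarray(v).size >= 2})
                if gc is not None:
                    row = {"model": model, "parameter": pn, "anova_p": gc.anova_p}
                    for pair, padj in gc.tukey_pairwise.items():
                        row["tukey_p_" + "_vs_".join(sorted(pair))] = padj
                    group_rows.append(row)
            # combined parameters via logistic regression
            if feats_pos and all(p.size >= 2 for p in feats_pos) and all(n.size >= 2 for n in feats_neg):
                X = np.vstack(
                    [np.column_stack(feats_pos), np.column_stack(feats_neg)]
                )
                y = np.concatenate([np.ones(feats_pos[0].size), np.zeros(feats_neg[0].size)])
                lc = _safe(logistic_combine, X, y)
                if lc is not None:
                    roc_rows.append(
                        {"model": model, "parameter": "combined",
                         "auc": lc.roc.auc, "ci95_low": lc.roc.ci95_low, "ci95_high": lc.roc.ci95_high}
                    )
        tables["roc"] = pd.DataFrame(roc_rows)
        tables["group_comparison"] = pd.DataFrame(group_rows)
        report["roc"] = roc_rows
    return report, tables


def run_from_manifest(manifest_path, out_dir) -> Path:
    """Re-execute a run from its manifest (and phantom spec, if any)."""
    mp = Path(manifest_path)
    m = json.loads(mp.read_text())
    phantom = None
    if m.get("phantom_spec"):
        phantom = spec_from_yaml(mp.parent / m["phantom_spec"])
    cfg = PipelineConfig(
        phantom=phantom,
        dynamic_path=m["inputs"]["dynamic"],
        vfa_path=m["inputs"]["vfa"],
        blood_roi_path=m["inputs"]["blood_roi"],
        aif_csv_path=m["inputs"]["aif_csv"],
        roi_paths=m["inputs"]["rois"] or {},
        relaxivity_r1=m["relaxivity_r1"],
        hct=m["hct"],
        sd_multiplier=m["sd_multiplier"],
        models=tuple(m["models"]),
        seed=m["seed"],
    )
    return run_pipeline(cfg, out_dir)
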