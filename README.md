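# dce2tcm

Quantitative pharmacokinetic analysis of dynamic contrast-enhanced (DCE)
MRI, built for prostate imaging but generic in its machinery. The package
fits, voxel by voxel, the **standard Tofts model** and a **spatial
two-tissue compartment model (2TCM)** to contrast-agent concentration
curves, generates parametric maps, applies the cancer-referenced
"false-positive ROI" selection rule, and evaluates the resulting parameters
as cancer-vs-normal biomarkers (paired t-test on fit RMSE, Pearson
correlations, one-way ANOVA with Tukey HSD, ROC/AUC with Hanley–McNeil
95% CI, and binary logistic regression for combined parameters). A digital
phantom with exact ground truth stands in for patient data, so the entire
chain is testable end to end.

## Models

With plasma concentration C_p(t) (the arterial input function, AIF) and
tissue concentration C(t), both in mM and time in minutes:

**Standard Tofts** — one well-mixed extravascular extracellular space (EES):

    C(t) = K^trans ∫₀ᵗ C_p(τ) e^{−(t−τ) k_ep} dτ,    k_ep = K^trans / v_e

**Two-tissue compartment model** — one fast and one slow exchanging
compartment per voxel:

    C(t) = ∫₀ᵗ C_p(τ) [ K₁^trans e^{−(t−τ) k¹_ep} + K₂^trans e^{−(t−τ) k²_ep} ] dτ

Fitting uses the asymmetric parameterisation K₂^trans = ε·K₁^trans,
k²_ep = k¹_ep + λ with λ ≥ 0, which makes the fit unique; reported
parameters are re-ordered so K₁^trans is always the larger amplitude. The
AIF is obtained from a blood ROI as C_p = C_b/(1 − Hct) with Hct = 0.42.
Concentration comes from the dynamic SPGR signal via the gradient-echo
signal equation, with pre-contrast T1 measured by a variable-flip-angle
(VFA) acquisition (3°–30°, six angles).

The kinetic fitters are scikit-learn-style estimators (`ToftsModel`,
`TwoCompartmentModel`, `VFAT1Mapper`) with plain-function wrappers
(`fit_tofts`, `fit_2tcm`, `fit_vfa_t1`, …).

## Worked example

```python
import numpy as np
import dce2tcm as d

# synthesize the default study: 60 frames at 8.3 s, flip 10°, six VFA angles
spec = d.default_spec(seed=7)
spec.noise_sd = 0.01 * d.baseline_signal(spec)      # 1% of baseline signal
ph = d.build_phantom(spec)

t1map = d.fit_vfa_t1(ph.vfa)                        # VFA T1 mapping
conc = d.signal_to_concentration(ph.dynamic, t1map) # SPGR inversion -> mM
aif = d.extract_aif(conc, ph.roi_masks["blood"])    # Cp = Cb / (1 - 0.42)

v = tuple(np.argwhere(ph.roi_masks["cancer"])[0])   # one cancer voxel
tofts = d.fit_tofts(conc.c_mM[v], aif)
tcm = d.fit_2tcm(conc.c_mM[v], aif)
print(f"Tofts : Ktrans={tofts.params.ktrans:.3f} kep={tofts.params.kep:.3f} "
      f"RMSE={tofts.rmse:.4f} mM")
print(f"2TCM  : K1trans={tcm.params.k1trans:.3f} kep1={tcm.params.kep1:.3f} "
      f"K2trans={tcm.params.k2trans:.3f} kep2={tcm.params.kep2:.3f} "
      f"RMSE={tcm.rmse:.4f} mM")
```

prints

```
Tofts : Ktrans=0.246 kep=0.649 RMSE=0.0369 mM
2TCM  : K1trans=0.248 kep1=1.215 K2trans=0.051 kep2=0.205 RMSE=0.0028 mM
```

The ground truth for this voxel is K₁^trans = 0.25, k¹_ep = 1.2,
K₂^trans = 0.05, k²_ep = 0.2 min⁻¹: the 2TCM recovers all four rates and
fits the curve an order of magnitude better (RMSE 0.0028 vs 0.0369 mM)
than the single-compartment Tofts fit, whose k_ep lands between the two
true efflux rates — exactly the behaviour that motivates the richer model.

The same analysis runs from the shell:

```bash
dce2tcm run --out run1/ --seed 7 --noise-sd 0.31
```

writing NIfTI maps, an AIF CSV, ROI summaries, the false-positive ROI, and
`stats_report.json` (RMSE comparison, correlations, ANOVA/Tukey, ROC/AUC,
logistic combinations) plus a manifest that reproduces the run exactly.
Other subcommands (`simulate`, `t1map`, `concentration`, `aif`, `fit`,
`maps`, `rois`, `stats`) expose the individual stages.

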