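# Methods

## Tracer-kinetic models

Both models relate the tissue contrast-agent concentration C(t) (mM) to
the plasma input C_p(t) through convolution with exponential efflux
kernels. The standard Tofts model assumes a single well-mixed EES
compartment with transfer constant K^trans (min⁻¹) and efflux rate
k_ep = K^trans/v_e. The two-tissue compartment model (2TCM) assumes each
voxel contains two non-communicating sub-compartments — one fast, one slow
— so the impulse response is a sum of two exponentials with amplitudes
K₁^trans, K₂^trans and rates k¹_ep, k²_ep. Neither model carries a plasma
volume (vp) term: C(t) is purely extravascular, consistent with the model
equations as written, and blood voxels are treated separately.

Because swapping the two compartments leaves the 2TCM curve unchanged, the
model is fitted in an asymmetric parameterisation
(K₁^trans, k¹_ep, ε, λ) with K₂^trans = ε·K₁^trans, k²_ep = k¹_ep + λ and
λ ≥ 0, which pins the labels inside the optimizer. After fitting, the
conventional ordering — K₁^trans is the larger amplitude, carrying its
paired rate as k¹_ep — is restored (`canonicalize_2tcm`). Amplitude ties
are broken by assigning the larger rate to position 1 (the "fast" label);
the raw record is preserved up to that relabelling, and the operation is
idempotent.

## Exact exponential convolution

`exp_convolve` computes ∫₀ᵗ c_p(τ)e^{−k(t−τ)}dτ exactly for the piecewise-
linear interpolant of the sampled AIF, by the standard per-interval
recursion: each interval contributes c₀·A + slope·B with
A = (1−e^{−kΔt})/k and B = (Δt−A)/k, accumulated under the decay factor
e^{−kΔt}. This is exact at the coarse clinical sampling (8.3 s) where FFT
or trapezoid convolution would dominate the fit error. Numerical care:
A uses `expm1`; B switches to its series Δt²/2 − kΔt³/6 for kΔt < 1e-5
(cancellation); the accumulated form uses a cumulative sum with
exponential weights, falling back to a sequential update when k·T > 600
would overflow the weights. k = 0 reduces exactly to the cumulative
trapezoid integral.

## Fitting

Per-curve fits are bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e-10, residuals in
concentration space). Bounds: K^trans ∈ [0, 5], k_ep ∈ [0, 10], ε ∈ [0, 100],
λ ∈ [0, 10] (min⁻¹ where applicable) — generous for prostate physiology
without flat tails. The Tofts fit starts from a peak-ratio heuristic. The
2TCM start list contains the fitted Tofts solution with ε = 0, a copy with
ε = 0.1, and three seeded jittered starts; the lowest-SSE candidate wins.
Because the un-optimized Tofts point itself is a candidate (ε = 0 gives
bitwise-identical residuals to the Tofts fit), the 2TCM RMSE can never
exceed the Tofts RMSE — the nesting property holds with certainty, which
is why RMSE(2TCM) ≤ RMSE(Tofts) on 100% of voxels in every run. An
all-zero curve short-circuits to a zero-amplitude fit with RMSE 0.
Jitter is seeded per voxel from its linear grid index, so parametric maps
are independent of voxel visiting order.

## Relaxometry

SPGR signal: S = M₀ sin α (1−E₁)/(1−E₁ cos α), E₁ = e^{−TR/T1}. VFA T1
mapping linearizes S/sin α = E₁·S/tan α + M₀(1−E₁) (slope = E₁) and then
polishes with a bounded nonlinear SPGR fit (on by default; it removes the
small bias of the linearized estimator under noise). Voxels whose slope
falls outside (0, 1), or whose T1 lands outside (0.1 ms, 20 s), are flagged
invalid — never silently zeroed. T1 estimates are invariant to global
signal scaling.

Concentration conversion inverts the SPGR equation frame by frame:
M₀ is calibrated from the baseline-average signal and the measured T10,
then E₁(t) = (1−y)/(1−y cos α) with y = S/(M₀ sin α), R1(t) = −ln E₁/TR,
and C(t) = (R1(t) − R10)/r1. Frames whose signal falls outside the
invertible range (E₁ ∉ (0,1)) become NaN and are excluded from fitting.
Baseline = the frames before bolus arrival (default 4 frames ≈ 30 s at
8.3 s/frame). Relaxivity defaults to r1 = 5.5 s⁻¹mM⁻¹ (gadobenate at 3 T);
every validation here is a round trip through the same constant, so
conclusions do not depend on its exact value.

## AIF

The plasma input is derived from a blood ROI as the unweighted voxel mean
of C_b(t) per frame, divided by (1 − Hct) with Hct = 0.42. No
partial-volume, inflow or dispersion correction is applied. For synthesis,
a population bolus model replaces the patient-measured AIF: a unit-area
gamma-variate first pass (area 3.7 mM·min, α = 2.5, β = 0.18 min) plus a
recirculation/washout term 0.8·(1−e^{−t'/0.3})e^{−t'/6} mM, delayed by a
30 s arrival. This peaks at ≈5.6 mM about 28 s after arrival and decays to
a slowly washing plateau — representative of a standard-dose bolus at
3 T. Its integral has a closed form (regularized lower incomplete gamma
plus elementary exponentials), which the tests use as an oracle.

## Digital phantom

The phantom emulates the target acquisition: 60 dynamic frames at
8.3 s/frame, TR 4.6 ms, flip 10°, plus a six-angle VFA series (3°, 5°,
10°, 15°, 20°, 30°) at TR 12 ms. A 32×32×3 grid carries square tissue
blocks on slices 0–1 (slice 2 is deliberately empty to exercise slice
gating):

| region | model | parameters (min⁻¹) | T10 (s) |
|---|---|---|---|
| cancer | 2TCM | K₁=0.25, k¹=1.2, K₂=0.05, k²=0.2 | 1.6 |
| normal_pz | 2TCM | K₁=0.10, k¹=0.45, K₂=0.02, k²=0.10 | 1.4 |
| normal_tz | Tofts | K=0.05, k=0.30 | 1.4 |
| false_positive | 2TCM | K₁=0.20, k¹=0.25, K₂=0.10, k²=0.90 | 1.5 |
| blood | — | C_b = (1−Hct)·C_p | 1.9 |

Cancer exchanges faster than normal tissue in both compartments. The
false-positive region has a cancer-like total transfer (its Tofts K^trans
is high) but its dominant amplitude sits on a slow rate — so the Tofts map
flags it while the fast-compartment amplitude does not, reproducing the
qualitative dissociation that makes such regions diagnostically
interesting. The forward chain is: true kinetics → C(t) → R1(t) = 1/T10 +
r1·C(t) → SPGR signal → noise. Noise is Gaussian on the magnitude signal
by default (Rician optional; at SNR > 20 the two agree to well under 2% in
fitted parameters), with `noise_sd` in absolute signal units;
`baseline_signal(spec)` returns the noiseless pre-contrast tissue signal
so "1% noise" conditions can be stated precisely. Identical spec + seed
give bit-identical arrays.

What the phantom does **not** emulate: anatomical geometry, B1/coil
inhomogeneity, motion, water–fat separation artifacts, partial-volume
mixing at region borders, inter-voxel parameter heterogeneity within a
region, and AIF measurement error. Passing round-trip tests therefore
demonstrates the correctness of the estimation chain under its own model
assumptions, not clinical accuracy on patient data.

## Maps, ROIs, false-positive rule

Maps are generated only for slices carrying ROIs; unfitted voxels hold NaN
(never 0, a legal rate). ROI summaries are unweighted means over fitted
voxels. The false-positive ROI rule: cutoff = mean(K^trans over the cancer
ROI) − m·SD (sample SD, n−1; multiplier m configurable, default 1 —
reading the rule's "standard deviations" as one SD); candidate voxels at
or above the cutoff are selected, so the selected ROI's mean K^trans is
close to the cancer mean by construction. Selection is monotone in the
candidate set; an empty selection warns rather than raises.

## Statistics

Voxel-level pairing is used for the RMSE paired t-test, and voxel-level
groups for ANOVA/ROC on the phantom (the synthetic study has too few
distinct ROIs for ROI-level inference; with patient cohorts the same
functions apply at ROI level). Tukey HSD uses the studentized-range
distribution with the Tukey–Kramer correction for unequal group sizes
(statsmodels). AUC is the normalized Mann–Whitney U with ties counted ½;
its 95% CI uses the Hanley–McNeil variance. Logistic combination is an
unregularized maximum-likelihood fit with intercept (Newton/IRLS); the
combined score is the in-sample linear predictor (no cross-validation),
and perfect separation is flagged as non-converged while the AUC of the
final predictor is still reported.

## Problem sizes and numerical choices in the validation battery

The acceptance battery uses the full 32×32×3 phantom (288 tissue voxels,
60 frames) for noiseless recovery and for the 1%-noise nesting/biomarker
checks; 1000 random parameter sets for the two-form equivalence (≤1e-12);
100 random AIFs for the convolution oracle; 500 replicates for the VFA T1
Monte Carlo; 10⁴ scores per class × 3 seeds for the binormal ROC check;
and a 16×16×2 phantom for the bitwise determinism check. The brute-force
convolution oracle is itself a trapezoid rule with O((kΔt/refine)²) error,
so it is compared at 100× refinement for slow-to-typical rates and 1000×
refinement for fast rates, keeping the oracle's own error below the 1e-6
comparison tolerance throughout.

## Known limitations

- Fitting is purely per-voxel; no spatial regularisation.
- The 2TCM as implemented has no plasma-volume or flow terms (it is not
  the 2CXM); model comparison is by RMSE, not information criteria.
- The SPGR inversion assumes perfect spoiling, a single flip angle across
  the volume, and no T2* decay.
- Rician noise is only treated generatively; fitting assumes symmetric
  residuals, which is why the Gaussian≈Rician agreement is claimed only at
  high SNR.
- With slow rates (k²_ep ≈ 0.1 min⁻¹) and an 8.3-minute window, the slow
  compartment is weakly identified under noise: amplitude errors of tens
  of percent for the smallest parameters are expected and visible in the
  noisy-phantom recovery table.
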