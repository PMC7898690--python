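# Methods

## Forward model and estimator

Tissue curves are generated by the extended Tofts model

    C_t(t) = v_p C_p(t) + Ktrans ∫₀ᵗ C_p(τ) e^{−kep (t−τ)} dτ,   kep = Ktrans / v_e.

The model includes backflux, which matters here because the protocols of
interest sample up to 30–40 minutes after injection. Time is in minutes
with t = 0 at injection start; concentrations in mM.

Estimation uses the Patlak linearization: for sample times t_j,

    x_j = ∫₀^{t_j} C_p dτ / C_p(t_j),   y_j = C_t(t_j) / C_p(t_j),

and an **unweighted** ordinary-least-squares line through the (x_j, y_j):
slope = K_i, intercept = v_p. The precontrast point (0/0) is excluded.
Negative concentrations produced by noise are kept, so the linear
estimator stays unbiased. Because Patlak neglects backflux, K_i
systematically underestimates Ktrans; to first order in kep the relative
bias is −kep × (a C_p-weighted mean tracer age), so it deepens with later
sampling and with larger Ktrans. This is a property of the estimand, not
an implementation artifact, and the phantom's recovery report therefore
scores the pipeline against the *noiseless Patlak value* of each tissue
class rather than against Ktrans.

## Default parameters

| parameter | default | units | rationale |
| --------- | ------- | ----- | --------- |
| Ktrans WM / GM | 5.0e-4 / 8.0e-4 | min⁻¹ | normal-appearing white/gray matter leakage scale |
| v_p WM / GM | 0.036 / 0.049 | — | plasma volume fractions of the same tissues |
| v_e | 0.05 | — | extravascular-extracellular fraction; sets backflux via kep |
| impaired leakage | +20 % on Ktrans | — | typical group effect size in cerebrovascular disease |
| r₁ | 4.2 | mM⁻¹s⁻¹ | gadobutrol longitudinal relaxivity at 7 T |
| Hct | 0.45 | — | venous hematocrit for blood→plasma conversion |
| tissue noise σ | 2.0e-3 | mM | concentration-domain noise of high-field T1-map protocols |
| first / last map | 4:20 / 30:00 | min | protocol window under study (phantom default: last map 25 min) |
| Monte-Carlo runs | 250,000 | — | K_i-SD standard error ≈ 0.14 %; a 25,000-run fast mode exists |

### Vascular input function

The venous (superior sagittal sinus) input function of a slow-infusion
protocol is modelled parametrically: zero until t₀ = 0, a rise to
a_peak = 1.5 mM at t_peak = 0.93 min (the 30th dynamic volume at 1.86 s
spacing), then mono-exponential washout at m = 0.03 min⁻¹. The rise is
linear by default (a gamma-variate option exists). All four parameters
are config-exposed because *absolute* K_i standard deviations scale with
the VIF amplitude; ratio metrics (e.g. the 2-map/7-map SD ratio) and the
noiseless bias are provably invariant under amplitude scaling, which the
suite asserts to 1e-8.

The washout rate and v_e jointly determine the backflux bias. With the
defaults (v_e = 0.05, m = 0.03 min⁻¹) the noiseless two-point bias for
the 4:20/25-min scheme is −14.0 % (WM) and −21.3 % (GM); scanning the
washout over m ∈ [1e-4, 0.1] min⁻¹ moves the WM value only within
[−13.1 %, −16.0 %], i.e. the bias is dominated by kep, not by the washout
shape. Reported in vivo-calibrated biases that are ~35 % smaller than
these correspond to an effective v_e ≈ 0.08; because v_e is a modelling
input here, the package keeps v_e = 0.05 and documents the sensitivity
rather than retuning it.

## Simulation noise model

Gaussian noise (SD σ) is added to the tissue concentrations only; the
plasma curve is treated as noiseless (it is measured from a large-ROI
average at high blood concentration, so its error is comparatively
negligible). The per-point Patlak ordinate error is then σ/C_p(t_j) —
heteroscedastic, growing as the input function washes out. Since the OLS
slope is linear in the noise, the estimator's SD has the exact closed
form

    SD(K_i) = σ sqrt( Σ_j ((x_j − x̄)/S_xx / C_p(t_j))² ),

implemented as `analytic_ki_sd` and used both for deterministic
monotonicity checks and as an independent oracle for the Monte-Carlo SD
(they agree to ~1 % at 10⁵ runs).

A consequence worth knowing: SD(K_i) is **not** strictly monotone in the
number of maps. Going from two maps to three adds a mid/late point whose
ordinate noise (∝ 1/C_p) is high, and under *unweighted* OLS this raises
the SD slightly (+3.3 % at the default washout; exactly neutral for a
flat plasma tail) before the expected decrease from four maps on. The
endpoint comparison still favours continuous scanning: the 2-map/7-map SD
ratio is 1.23 at defaults.

## In vivo-style pipeline

* **Blood curve**: per-volume spatial mean over the venous ROI of the
  dynamic series; divided by (1 − Hct).
* **Plasma model**: log-linear mono-exponential fitted to the last
  dynamic point plus the map-derived blood points; the cumulative plasma
  integral is trapezoidal over the measured segment (anchored at t = 0)
  and analytic over the fitted tail. A negative fitted washout rate is
  clamped to zero and flagged.
* **Maps**: per voxel, T1→concentration at each postcontrast time, then
  the same Patlak OLS as in simulation. Non-positive or non-finite T1
  voxels become NaN ("no data") and are excluded from counts — never
  silently propagated.
* **ROI statistics**: "central 95 %" percentile trimming — voxels outside
  the [2.5, 97.5] percentiles of the ROI's own distribution are dropped
  before mean/SD. (A literal 95 % confidence interval of the mean would
  reject nearly all voxels; percentile trimming is the outlier-robust
  reading and is flagged here as an interpretation.)
* **WM vs GM**: paired two-sided Wilcoxon signed-rank. The default is the
  normal approximation *without* continuity correction, because with
  n = 5 subjects the exact two-sided p can never go below 2/2⁵ = 0.0625;
  an exact mode is provided and is verified against full 2ⁿ sign
  enumeration for n ≤ 8. Ties and zero differences follow the usual
  discard/midrank conventions; an all-zero difference vector raises.

## Digital phantom

The phantom emulates the acquisition geometry the pipeline expects: a
precontrast T1 volume, a 90-volume dynamic series at 1.86 s spacing with
three pre-injection volumes and bolus peak at 0.93 min, two (or more)
postcontrast T1 maps at the scheme times, and disjoint WM/GM/SSS masks on
a 32³ grid (1728 WM and 2368 GM voxels — enough for class-mean
tolerances of a few per mil). Postcontrast T1 is computed by exactly
inverting the linear ΔR₁ relation, so at zero noise the pipeline recovers
the programmed per-class Patlak values to < 1e-6 relative — the round
trip isolates pipeline defects from model error.

Noise is additive Gaussian on T1 for the maps (per class, calibrated
first-order so the concentration-domain noise is 2.0e-3 mM; at ~1 %
relative T1 noise the linearization error is negligible, and the
per-voxel K_i spread matches the protocol simulator's closed form within
10 %) and additive Gaussian (0.02 mM) on the dynamic blood series.
Baseline T1 values (WM 1.2 s, GM 2.0 s, blood 2.4 s) are plausible 7 T
numbers but only ΔR₁ enters the math.

What the phantom does **not** emulate: anatomy (geometry is nested
blocks), Rician signal statistics, motion, partial-volume mixing at the
0.7 mm/1.2 mm resolution difference between pre- and postcontrast maps,
B1 inhomogeneity, and T2* effects during the bolus. Passing phantom
tests therefore demonstrates correctness of the numerical pipeline under
the stated noise model, not robustness to those acquisition artifacts;
registration and segmentation quality are likewise assumed.

## Numerical choices

* Convolution and plasma integrals on a dense uniform grid, step 0.5 s
  (config-exposed); trapezoid rule throughout. The dynamic spacing is
  1.86 s, so the grid oversamples every measured feature; the linear-rise
  segment is integrated exactly.
* r₁ is applied directly in s⁻¹mM⁻¹ against 1/T1 in s⁻¹; kinetic times
  stay in minutes (no unit conversion of the time axis is needed).
* Mono-exponential fits are log-linear least squares: deterministic and
  closed-form, which is appropriate for the three-point plasma tail.
* One root seed spawns independent child streams per sweep row
  (`numpy.random.SeedSequence.spawn`), so any table row is individually
  reproducible and rows are statistically independent.
* Problem sizes: sweeps default to 250,000 runs per condition (the full
  two-experiment sweep is a few seconds, vectorized); the phantom default
  is a 32³ grid with two postcontrast maps.

## Known limitations

* The parametric VIF is a stand-in for a measured venous curve; absolute
  SD values should only be compared across schemes, not across VIFs.
* Unweighted Patlak OLS is deliberately simple; a 1/C_p²-weighted fit
  would remove the 2→3-map SD anomaly and slightly improve precision, but
  is not what the sparse-protocol analysis under study uses.
* The exact Wilcoxon mode relies on tie-free data for strict equality
  with enumeration; heavy ties at tiny n should be interpreted with care.
* `fit` expects co-registered volumes; no resampling is performed
  internally.
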