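# sparsedce

Quantification of **subtle blood–brain-barrier (BBB) leakage** from a
*sparsely time-sampled* DCE-MRI protocol built on quantitative T1 maps,
plus the Monte-Carlo machinery to design such a protocol.

Healthy-tissue BBB leakage is tiny (K_i ≈ 5–8 × 10⁻⁴ min⁻¹), so
conventional rapid dynamic T1-weighted scanning spends a long acquisition
on information that accrues very slowly. Because gadolinium extravasation
is slow, a protocol that acquires only a *few* quantitative T1 maps — one
precontrast, a short dynamic scan over the bolus to capture the venous
input function, and two (or more) postcontrast maps up to tens of minutes
after injection — can recover K_i with nearly the same precision as
continuous scanning, freeing the scanner for other sequences in between.
This package is aimed at researchers designing or analysing such
protocols (7 T MP2RAGE-style acquisitions in particular).

## Model

Tissue concentration follows the extended Tofts model

```
C_t(t) = v_p·C_p(t) + Ktrans ∫₀ᵗ C_p(τ)·exp(−(Ktrans/v_e)(t−τ)) dτ
```

with plasma volume fraction `v_p`, extravascular-extracellular fraction
`v_e`, and transfer constant `Ktrans` (the "true" leakage rate). T1 maps
convert to concentration through the linear relaxation relation
`ΔR₁ = 1/T1_post − 1/T1_pre = r₁·C` (r₁ = 4.2 mM⁻¹s⁻¹ by default);
whole-blood values convert to plasma via `C_p = C_b/(1 − Hct)`
(Hct = 0.45). Estimation uses the Patlak plot: `y = C_t(t)/C_p(t)`
against normalized exposure `x = ∫₀ᵗC_p dτ / C_p(t)`; the regression
slope is the leakage rate **K_i** and the intercept **v_p**. Patlak
ignores backflux, so K_i underestimates Ktrans by an amount growing with
`kep = Ktrans/v_e` and with the sampling time — the package quantifies
exactly this accuracy/precision trade-off.

## Modules

| module         | contents |
| -------------- | -------- |
| `pk_models`    | extended Tofts forward model, Patlak coordinates + OLS fit, T1↔concentration and blood→plasma conversions, mono-exponential fitting |
| `protocol_sim` | vectorized Monte-Carlo simulator; sweeps over the number of postcontrast maps and the last-map time; exact closed-form SD of the K_i estimator |
| `quantify`     | in vivo-style pipeline: venous blood curve extraction, plasma-tail model, voxelwise K_i/v_p maps, central-95 % trimmed ROI statistics, paired Wilcoxon WM-vs-GM comparison |
| `phantom`      | digital phantom (NIfTI-compatible volumes, 90-volume dynamic series, masks) with known ground truth and noise calibrated to 2 × 10⁻³ mM in the concentration domain |
| `cli_io`       | YAML config validation, NIfTI I/O, and the `sparsedce` command line |

## Worked example — is a second map worth it?

```python
import dataclasses
from sparsedce import SimulationConfig, WM, make_scheme, run_monte_carlo

two_map = SimulationConfig(tissue=WM, n_runs=250_000, seed=1)   # maps at 4:20 and 30 min
seven_map = dataclasses.replace(
    two_map, scheme=make_scheme(two_map.scheme.first, 30.0, 5), seed=2
)
s2, s7 = run_monte_carlo(two_map), run_monte_carlo(seven_map)
print(f"2 maps : mean Ki = {s2.mean_ki:.3e}  SD = {s2.sd_ki:.3e}  bias = {s2.pct_diff:+.1f}%")
print(f"7 maps : mean Ki = {s7.mean_ki:.3e}  SD = {s7.sd_ki:.3e}  bias = {s7.pct_diff:+.1f}%")
print(f"precision ratio (2-map SD / 7-map SD) = {s2.sd_ki / s7.sd_ki:.2f}")
```

```
2 maps : mean Ki = 4.172e-04  SD = 8.095e-05  bias = -16.6%
7 maps : mean Ki = 4.170e-04  SD = 6.587e-05  bias = -16.6%
precision ratio (2-map SD / 7-map SD) = 1.23
```

Dropping from seven to two postcontrast maps costs only a factor ~1.2 in
precision and essentially nothing in accuracy; the residual −16.6 % bias
at a 30-min last map is the deterministic Patlak backflux underestimate,
not a noise effect (it is identical for both schemes).

The same round trip through the full voxelwise pipeline on the digital
phantom:

```python
from sparsedce import PhantomSpec, make_phantom, run_pipeline, recovery_report

ds = make_phantom(PhantomSpec(seed=42))          # 32³ grid, default noise
ki, vp, plasma = run_pipeline(ds)                # blood curve → plasma tail → Patlak maps
print(recovery_report(ds, ki, vp)[
    ["tissue", "true_ktrans", "noiseless_ki", "recovered_ki_mean", "rel_error_ki"]
].to_string(index=False))
```

```
tissue  true_ktrans  noiseless_ki  recovered_ki_mean  rel_error_ki
    WM       0.0005       0.00043           0.000429     -0.003352
    GM       0.0008       0.00063           0.000631      0.002049
```

`noiseless_ki` is the estimand of the pipeline (Ktrans minus the known
backflux bias for the 4:20/25-min two-map scheme); the recovered class
means land within a fraction of a percent of it.

Command-line equivalents: `sparsedce simulate-protocol`,
`sparsedce optimize-timing`, `sparsedce make-phantom`, and
`sparsedce fit` (voxelwise maps from NIfTI inputs). See `--help`.

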