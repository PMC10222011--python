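# pfmetallome

Method validation and trace-element profiling for ICP-MS/MS assays of
peritoneal fluid (and similar low-volume biofluids), built around a seeded
synthetic-instrument simulator.

Quantifying a 20-element panel (Li, Ti, V, Cr, Mn, Fe, Co, Ni, Cu, Zn, As,
Rb, Sr, Mo, Cd, Sn, Ba, La, Pb, Bi) in peritoneal fluid by inductively
coupled plasma tandem mass spectrometry is hard for two reasons: the
protein/salt matrix suppresses or enhances analyte signal relative to
aqueous standards (a *matrix effect*), and polyatomic ions formed from the
matrix or the plasma gas (e.g. ⁴⁰Ar¹⁶O⁺ on ⁵⁶Fe⁺, ⁴⁰Ar¹²C⁺ on ⁵²Cr⁺) share
the analyte's mass-to-charge ratio (*spectral interference*).  This package
implements the full in-house validation and reporting chain a lab uses to
establish such an assay, for method developers and analysts who need the
statistics reproducible and testable:

* **Internal standardization** — calibration on the ratio of analyte to
  internal-standard signal (Sc, Ge, Rh, Re at 40 µg L⁻¹), `y = I_a/I_IS`
  against `x = C_a/C_IS`, so drift and introduction-efficiency variation
  cancel; curves accepted at R² > 0.995.
* **Detection limits** — LOD = 3·s_b/m, LOQ = 10·s_b/m from the standard
  deviation of 10 consecutive blank ratios and the calibration slope.
* **Spike recovery** — R% = 100·(I_spiked − I_unspiked)/I_standard, with a
  ±10 % tolerance interval (90–110 %); dilution factors 1:2 and 1:4 are
  compared and the collision-gas (He) and no-gas acquisition modes are
  classified per element.
* **Uncertainty budget** — a one-way ANOVA over a 5-replicate × 4-day
  spiked grid gives repeatability and intermediate precision
  (s_rep = √MS_within, s_ip = √((MS_between − MS_within)/n_rep));
  with trueness u_t = (100/C)·√(RMS_bias² + u_conc² + u_prep²) the expanded
  relative uncertainty is U = k·√(u_rep² + u_ip² + u_t²), k = 2.
* **Cohort profiling** — per-element acquisition-mode routing (He for the
  interference-prone Cr, Cu, Fe, Zn; arsenic excluded as not accurately
  measurable in either mode), left-censoring against LOD/LOQ, and summary
  statistics over quantified samples only.

Because no raw instrument data are published for assays of this kind, the
`instrument` module is a first-class, tested signal simulator that emits
every dataset the pipeline consumes — calibration series, blanks,
dilution-study and validation spikes, and a 20-sample cohort — with linear
response, residual matrix effects, mode-specific polyatomic interference,
day drift, day-level preparation effects, and multiplicative-plus-shot
noise, all driven by one seed.

## Worked example

```python
import pfmetallome as pm

cfg = pm.PipelineConfig(design=pm.RunDesign(seed=1))
bundle = pm.run_pipeline(cfg)

lod = bundle["limits"].pivot(index="element", columns="mode", values="lod_ugL")
print("Fe LOD  no-gas %.2f ug/L   He %.2f ug/L" % (lod.loc["Fe", "no-gas"], lod.loc["Fe", "He"]))

inter = bundle["interday_recovery"].pivot(index="element", columns="mode", values="recovery_pct")
print("Fe interday recovery  no-gas %.0f%%   He %.1f%%" % (inter.loc["Fe", "no-gas"], inter.loc["Fe", "He"]))
print("1:%g dilution recommended" % bundle["run_log"]["recommended_dilution_factor"])
print(bundle["budgets"][["element", "mode", "u_ip", "u_rep", "u_t", "U"]].head(6).to_string(index=False))
```

prints

```
Fe LOD  no-gas 2.17 ug/L   He 0.11 ug/L
Fe interday recovery  no-gas 9972%   He 96.6%
1:4 dilution recommended
element   mode  u_ip  u_rep  u_t    U
     Ba no-gas   1.2    1.4  6.1 12.7
     Bi no-gas   0.9    1.3  4.9 10.4
     Cd no-gas   2.0    1.1  4.7 10.4
     Co no-gas   1.6    1.4  4.8 10.5
     Cr     He   1.0    1.1  7.5 15.2
     Cu     He   0.8    2.3  5.2 11.5
```

Read: the ⁵⁶Fe blank is inflated ~20× in no-gas mode by the ArO⁺/CaO⁺
overlap, and its apparent spike recovery there is absurd (~10 000 %); the
collision gas restores both the detection limit (0.11 µg L⁻¹) and the
recovery (96.6 %, inside the 90–110 % tolerance band).  The budget columns
are the relative standard-uncertainty contributions in percent; trueness
(u_t) dominates each budget, and the expanded uncertainties sit in the
10–17 % range typical of spike-validated biofluid assays.

The same stages are available from the shell:

```sh
pfmetallome simulate --seed 1 --out records.csv
pfmetallome run-all --records records.csv --seed 1 --out-dir report/
```

`report/` then holds `curves.csv`, `limits.csv`, `dilution_recovery.csv`,
`interday_recovery.csv`, `budgets.csv`, `mode_agreement.csv`,
`cohort_results.csv`, `cohort_summary.csv` and a machine-readable
`run_log.json` (versions, seed, config hash).

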