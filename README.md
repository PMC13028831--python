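# gonadnmr

Chemometric analysis of ¹H NMR spectra of sea-urchin (*Paracentrotus
lividus*) gonad extracts, for metabolomics researchers who want a tested,
scriptable re-implementation of the standard polar/apolar two-arm
workflow:

* **Polar arm (sex discrimination)** — full-resolution frequency-domain
  spectra are windowed (11.0 … −0.5 ppm), TSP-referenced and masked, then
  classified by PLS-LDA: NIPALS partial least squares scores with a
  pooled-covariance linear discriminant, validated by stratified k-fold
  CV and Monte Carlo CV.  Variable selection on the curated 72-resonance
  peak table uses Subwindow Permutation Analysis (SPA): Monte Carlo
  PLS-LDA sub-models with test-set value permutation give each variable a
  p-value and a Conditional Synergistic Score, COSS = −log₁₀(p);
  variables with p < 0.05 (COSS > 1.30) are selected and tested
  univariately with exact Mann–Whitney U.
* **Apolar arm (lipid indices)** — CDCl₃ lipid spectra are reduced to
  trapezoidal integrals of diagnostic windows A–J and F′ (F′ =
  2.37–2.40 ppm isolates DHA-associated α-methylenes), and a proton
  balance yields molar fractions: with chain count T = (A+B)/3,
  ω₃ = 100·A/(A+B), n = 100·(E/4)/T, h = 100·(F′/2)/T, s = 100 − n.
  Internal-consistency bounds drive automated QC flagging, and batches
  are summarised per sex with Mann–Whitney tests and a fish-oil benchmark
  block.

A synthetic-cohort generator with known ground truth (sex-shifted
metabolite concentrations, known lipid compositions) makes every stage
testable end to end; it ships the curated polar (72-entry) and apolar
(29-entry) peak tables as versioned, checksummed CSVs.

## Worked example

```sh
gonadnmr full --seed 1 --out demo/
```

simulates the default cohort (37 samples: 23 M, 14 F; 32,768-point
spectra) and runs both arms.  `demo/report.md` then contains, among other
lines:

```
- samples: 37 (23 M / 14 F)
- R2Y per LV: [0.8583, 0.0929, 0.0283, 0.0093, 0.0066, 0.0029] (cum 2 LV: 0.9513)
- CV (pareto): optLV=2, error_min=0.0270, sens=0.928..., spec=1.0, AUC=0.996...
- MCCV (auto): optLV=2, error_min=0.1212
- SPA: 14 selected variable(s) of 72 peaks
```

Reading this: the first latent variable already captures most of the
sex-related y-variance (R²Y₁ = 0.86); cross-validation supports a
two-component model with 2.7 % held-out misclassification, and the
Monte Carlo CV estimate is more conservative (12 %), as expected for a
37-sample cohort.  The top of `demo/spa_table.csv`:

```
peak_no,delta_ppm,metabolite,p_value,coss,selected,...
33,3.5648,Glycine,2.64e-25,24.58,True,...
37,3.9,Betaine (tentative),7.52e-14,13.12,True,...
35,3.7979,Alanine,5.87e-11,10.23,True,...
```

shows the seeded discriminants (glycine, betaine, alanine, …) dominating
the COSS ranking — the generator plants those effects, and SPA recovers
them.  The apolar table in the report gives per-index medians/IQRs with
sex-stratified p-values and reports the batch DHA median (≈1.6 mol%)
as *below* the fish-oil reference range (7.0–19.2 mol%), the expected
signature of sea-urchin gonad lipids.

The same pipeline runs on real data: point `--input-dir` at a directory
with `metadata.csv` (columns `id,sex,site,diameter_mm,height_mm,weight_g,
gonad_g,gsi_pct`) and per-sample two-column text spectra
`<id>_polar.txt` / `<id>_apolar.txt`.

## Library use

```python
from gonadnmr.synth import CohortConfig, LipidComposition, generate_apolar_spectrum
from gonadnmr.lipids import integrate_regions, solve_indices

cfg = CohortConfig(seed=0, noise_sd=0.0)
comp = LipidComposition(n_unsat=60, s_sat=40, omega3=20, dha=2)
li = solve_indices(integrate_regions(generate_apolar_spectrum(comp, cfg, seed=1)))
print(li.n_unsat, li.omega3, li.dha)   # 60.0 20.0 2.0 (exact round trip)
```

See `docs/methods.md` for the models, defaults and numerical choices.

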