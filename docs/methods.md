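# Methods

`gonadnmr` implements a two-arm ¹H NMR metabolomics analysis of sea-urchin
gonad extracts: supervised sex discrimination from polar (aqueous-buffer)
spectra, and lipid unsaturation indices from apolar (CDCl₃) spectra.  This
note documents the models, their assumptions, the tunable parameters, the
synthetic-data generator that stands in for the unavailable raw cohort,
and the numerical choices made where the design was genuinely open.

## Spectra and preprocessing

A spectrum is a processed frequency-domain trace: a strictly monotone
descending chemical-shift axis (ppm) with one real intensity per point,
windowed to 11.0 … −0.5 ppm.  Polar spectra are referenced by shifting
the axis so the maximum within ±0.1 ppm of 0 ppm (the TSP singlet) sits
at exactly 0.00 ppm; when two candidate points tie, the more downfield
one wins — an arbitrary but deterministic and documented rule.  Narrow
regions dominated by non-informative signals are excluded from feature
matrices before supervised modelling; the defaults are residual water
(4.70–5.00 ppm) and TSP ±0.05 ppm for polar spectra and residual CHCl₃
(7.24–7.30 ppm) for apolar spectra.  These bounds are configuration, not
data: the upstream protocol states that such regions were excluded but
not where, so the defaults are chosen to cover the usual culprits and are
overridable.

## PLS-LDA

Class labels are coded −1 (male) / +1 (female); the LDA threshold depends
on this coding, so it is fixed package-wide.  Columns are mean-centred
and optionally scaled — pareto (divide by √sd) or auto (divide by sd),
using the *sample* standard deviation — always with statistics computed
on the training partition only and re-applied to held-out rows.
Zero-variance columns under pareto/auto are dropped with a warning.

PLS1 components are extracted by NIPALS with per-component deflation
(for a single response the inner iteration converges in one step, so each
weight vector is `w_a = X_a'y_a / ‖X_a'y_a‖` on the deflated matrices).
Per component, R²X and R²Y are the fractions of the scaled-X and centred-y
sum of squares captured by that component; scores are mutually orthogonal
by construction.  If the residual rank is exhausted the model truncates
with a warning rather than emitting degenerate components.

The discriminant boundary is a two-class LDA in score space with pooled
within-class covariance and empirical priors (the class-imbalance
log-prior enters the threshold).  Priors were not stated upstream;
empirical priors are the standard default and match the cohort imbalance.

VIP follows the standard definition
`VIP_j = sqrt(V · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, so the mean of
the squared VIPs is exactly 1 — a useful identity that the tests assert
on every fitted model.

## Validation

k-fold CV uses stratified round-robin fold assignment (deterministic) and
refits scaling *and* the per-LV LDA inside each training fold; the per-LV
error curve pools all held-out predictions, and the optimal complexity is
the smallest component count attaining the minimum (parsimony tie-break —
unstated upstream, chosen because a flat error curve should not inflate
model complexity).  Monte Carlo CV repeats random stratified
train/test splits (defaults: 80 % train, 500 replicates, seeded) and
averages per-LV test error.

Sensitivity, specificity (female = positive class) and the rank-statistic
AUC (ties contribute ½) are reported at the optimum; with a single-class
truth vector the undefined rate is reported as absent, never as 0.

Leakage is the main practical hazard in this workflow.  Unsupervised
scaling leaks only weakly (it never sees labels), but supervised variable
selection performed outside the CV loop biases null-data error far below
chance; the test suite demonstrates this deliberately (full-data VIP
ranking before CV on pure-noise cohorts) and asserts that the proper
in-fold pipeline stays at chance.

## SPA / COSS

Subwindow permutation analysis runs on the 72-column peak-height matrix
derived from the curated polar resonance table, not on the full grid.
Per Monte Carlo iteration: a stratified sample subset (default 75 % of
each class) and a random variable subset (default `ceil(sqrt(V))` clipped
to [5, 15]) are drawn; an inner two-component PLS-LDA (matching the
validated complexity) is fitted with autoscaling on the sub-training
partition; the out-of-subset error is recorded once intact and once per
included variable with that variable's held-out values permuted across
test samples.  Permuting only the test partition keeps normal and
permuted errors paired on identical sub-models, which isolates each
variable's predictive contribution.  Per variable, the p-value is the
one-sided Mann–Whitney probability that permuted errors exceed normal
errors, and `COSS = −log10(p)` (p clamped at 1e-300 before the log).
Variables with p < 0.05 (COSS > 1.30) are selected.  Defaults: 1000
iterations, seeded; a variable never drawn raises an explicit budget
error instead of a silent gap.

## Mann–Whitney and boxplots

Group comparisons use the Mann–Whitney U test: the exact distribution of
U when the pooled sample is tie-free and n₁+n₂ ≤ 20, otherwise mid-ranks
with the tie-corrected, continuity-corrected normal approximation; the
method used is recorded in the result.  The implementation delegates to
`scipy.stats.mannwhitneyu` and is checked in the tests against a
from-scratch enumeration of all rank splits.  Boxplot statistics use
type-7 (linear-interpolation) quartiles and 1.5 × IQR whiskers placed at
the most extreme points inside the fences.

## Lipid indices

Eleven diagnostic windows (A–J and F′) are integrated by plain
trapezoidal quadrature on the native grid — no peak fitting — matching a
predefined-window integration protocol.  Only F′ (2.37–2.40 ppm) is fixed
numerically by the protocol; the other defaults are anchored to the
annotated motif positions (A 0.93–1.00, B 0.83–0.93, C 1.20–1.40,
D 1.55–1.72, E 1.95–2.15, F 2.28–2.36, G 2.70–2.90, H 4.05–4.35,
I 5.20–5.30, J 5.30–5.45 ppm) and are configuration.  J's window is
placed to minimise overlap with the sn-2 glycerol region I; a
triglyceride correction of J via H/I is plausible but not implemented,
because the historical nine-equation coefficients are not reprinted in
any source available to this package.  The solver is therefore a
documented reconstruction constrained by the stated outputs and bounds:

    T       = (A + B) / k_terminal          (k_terminal = 3)
    omega3  = 100 · A / (A + B)
    n_unsat = 100 · (E / k_E) / T           (k_E = 4)
    dha     = 100 · (F′ / k_F′) / T         (k_F′ = 2)
    s_sat   = 100 − n_unsat

The proton multiplicities live in one `Stoichiometry` table shared by the
generator and the solver, so correctness is testable independently of the
historical coefficients.  QC flags (never exceptions): any index outside
[0, 100]; dha > omega3; omega3 > n_unsat; any negative region integral;
an olefinic deficit J/2 < E/4 (fewer olefinic protons than unsaturated
chains).  Flagged spectra are excluded from summaries and listed in the
QC log.  Batch summaries report median/IQR per index, overall and per
sex, with two-sided Mann–Whitney tests, plus a benchmark block comparing
the batch medians with bundled fish-oil reference constants (DHA
7.0–19.2 mol%, median ≈ 14.0; ω-3 20.9–35.7 mol%, median ≈ 26.7).

## Synthetic-data generator

No public accession exists for the study cohort, so the generator is a
first-class, tested module that emulates its structure: 37 samples
(23 male, 14 female) with per-sex biometrics (test diameter, height, wet
weight, gonad weight; GSI computed from the drawn weights), one polar and
one apolar spectrum per sample on a 32,768-point grid over 11.0 … −0.5
ppm.

Polar spectra are sums of Lorentzian multiplets at the curated table
shifts: HWHM 0.003 ppm (≈1.2 Hz at 400 MHz, consistent with 0.3 Hz
exponential line broadening on natural linewidths), binomial stick
patterns (d 1:1, t 1:2:1, multiplets rendered as an unresolved five-stick
cluster), J = 7 Hz (0.0175 ppm) — a typical ³J(H,H); no coupling
constants were available.  Each multiplet's total area is concentration ×
protons; a TSP singlet anchors 0.00 ppm.  Concentrations are log-normal
per sample (default cv 0.3 — strictly positive, realistic inter-individual
spread), with half the log2 fold change applied to each sex.  The default
discriminant panel (glycine, alanine, creatine, betaine, TMAO, histidine,
lysine, |log2fc| 0.5–1.0) reproduces the qualitative ranking structure
needed for power tests; the magnitudes are placeholders — no absolute
concentrations or effect sizes were ever reported for this system.
Baseline is a low-order polynomial of default amplitude 0 (upstream
spectra are baseline-corrected).

Apolar spectra are composed from a known `LipidComposition`
(n_unsat + s_sat = 100 exactly; dha ≤ omega3 ≤ n_unsat; default 3 double
bonds per unsaturated chain, 90 % of chains esterified).  Region areas
follow the shared stoichiometry table (A = 3·ω₃, B = 3·(100−ω₃),
E = 4·n, F′ = 2·h, G = 2·(db−1)·n, J = 2·db·n, H/I from the glyceride
fraction, per 100 chains).  Diagnostic peaks are rendered as Lorentzians
*truncated to their own integration window* and renormalised on the
rendering grid, so each region's trapezoidal integral equals its
stoichiometric target exactly in the noise-free limit.  This is a
deliberate generator design choice: with untruncated Lorentzian tails,
cross-window leakage between the adjacent A/B windows alone biases the
recovered ω-3 fraction by more than the 0.5 mol% round-trip tolerance the
solver is held to, and the generator's job is to provide exact ground
truth, not to model lineshape physics.  A few out-of-window motifs
(sterol methyls, choline headgroups) are added for realism with compact
support so they never touch a diagnostic window.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: peak overlap between neighbouring metabolites,
pH- or matrix-dependent shift drift, realistic lineshape tails and
baseline distortions in the apolar diagnostic regions, correlated
metabolite pools, and any true effect sizes.  Tests on synthetic cohorts
certify the machinery (recovery, calibration, determinism), not the
biology.

## Problem sizes and determinism

Simulation-based tests use reduced problem sizes chosen for quick
iteration: 4–16 k grid points, 20 Monte Carlo replicates for calibration
and power checks, 120–300 SPA iterations and 20–50 MCCV replicates; the
full-size defaults (32 k grid, 1000 SPA iterations, 500 MCCV replicates)
remain the package defaults.  All randomness flows from explicit integer
seeds through `numpy.random.default_rng` / `SeedSequence.spawn`;
identical seeds reproduce cohorts and analysis outputs bit-identically,
and the CLI records the seed and a configuration hash in every report.

## Known limitations

* The lipid balance system is a reconstruction (see above); absolute
  agreement with the historical coefficient set is not claimed.
* The unique-metabolite count depends on documented name-collapsing rules
  and an explicit alias map for composite rows; ambiguous composites
  ("X and/or Y") are excluded rather than guessed.
* The exact Mann–Whitney path requires tie-free data; heavily tied inputs
  (e.g. SPA error samples) always use the tie-corrected approximation.
* Sensitivity/specificity at very small class sizes are coarse-grained;
  MCCV pooling mitigates but does not remove this.
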