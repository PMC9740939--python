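# Methods

This note documents the models, numerical choices and limitations behind
`herbipk`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Non-compartmental analysis

NCA treats the concentration–time curve as data, not as the output of a
structural model; the only model-like assumption is log-linear decline in
the terminal phase.

**Areas.** AUC0–t and AUMC0–t are piecewise trapezoidal integrals of C(t)
and t·C(t) over the usable points. The default rule is linear on every
segment. The `linear-up/log-down` option applies the log-trapezoid
(C₁−C₂)·Δt/ln(C₁/C₂) on strictly declining segments between positive
concentrations and falls back to linear otherwise; its AUMC counterpart is
(t₁C₁ − t₂C₂)·k + (C₁−C₂)·k² with k = Δt/ln(C₁/C₂). The linear rule is the
default because it is the convention of the mainstream NCA packages this
pipeline mirrors, and because it makes the integrated-profile AUC exactly
linear in the component concentrations (see below).

**Terminal slope.** λz is fitted by ordinary least squares of ln C on t.
Candidate windows are the trailing runs of k quantifiable points strictly
after Tmax, k from `min_points` (default 3, the smallest value for which
adjusted R² is defined) up to all post-Tmax points. The window with the
highest adjusted R² wins; exact ties go to the longer window (more data at
equal fit quality). Windows with non-negative slope are discarded; if none
remains the terminal phase is declared not estimable and all
extrapolation-dependent parameters are reported as missing rather than
guessed. When the strictly-post-Tmax tail has fewer than `min_points`
points, the Tmax point itself joins the candidate pool: for a profile that
declines monotonically from the first sample the peak belongs to the
terminal phase, and excluding it would make short late-sampled profiles
unanalysable. The stored adjusted R² is clipped to [0, 1] for reporting;
selection uses the raw value.

**BLQ policy.** Below-LLOQ observations before Tmax are kept as zero
(absorption has not started or has barely started, and dropping them would
bias early AUC upward); interior BLQ observations are treated as missing;
trailing BLQ observations are dropped from both integration and λz fitting.
This is the common bioanalytical convention.

**Units.** Time is hours throughout (the 5/15/30 min samples of the
emulated design are 0.083/0.25/0.5 h). With dose in mg/kg and
concentrations in ng/mL, CLz/F = Dose/AUC0–∞ carries a net ×10³ factor to
L/h/kg, and Vz/F = CLz/F/λz is in L/kg. Summary tables report
across-subject mean ± sample SD (ddof = 1), formatted to 4 significant
figures; machine-readable outputs keep full precision.

## AUC-weighted integration

Weights are proportional exposure shares, w_j = AUC_j/Σ_k AUC_k, computed
by default from AUC0–∞ (AUC0–t selectable). The denominator runs over all
supplied analytes, however many there are. Two scopes exist:

* `pooled-mean` (default): one weight vector from the across-subject mean
  AUC of each analyte, applied to every subject. A single-coefficient set
  is what a study report quotes, and pooling is the only way to obtain one.
* `per-subject`: each subject weighted by their own AUC vector.

The integrated curve is the pointwise convex combination of the component
curves on their shared nominal grid; no interpolation across mismatched
grids is attempted (the emulated design has one fixed schedule, and
resampling would silently manufacture data). BLQ component values enter the
sum as zero. For NCA of the integrated curve the effective LLOQ is
min_j w_j·LLOQ_j — any non-zero integrated concentration has at least one
quantifiable component, so this bound is attained.

Two identities anchor the test suite. Under the linear trapezoid the
integrated AUC0–t equals Σ_j w_j·AUC0–t,j *exactly, per subject* — but only
when every component is integrated over the same support. LLOQ censoring
truncates component supports at different last-quantifiable times, so the
exactness tests run on simulations with negligible LLOQ; with realistic
censoring the identity holds only approximately, which is a property of the
data, not of the code. Similarly, integrated Cmax ≤ Σ_j w_j·Cmax,j always
(convexity), while "integrated Tmax lies between the component Tmax values"
is guaranteed only for unimodal component curves: assay noise can break
unimodality, so that property is asserted on noise-free simulations.

Subjects missing any analyte (or missing an estimable AUC basis) are
excluded from the integrated stage with a logged warning rather than
imputed.

## Bioanalytical validation statistics

Calibration is weighted least squares of response ratio on nominal
concentration, default weights 1/x² (the standard choice when assay error
grows with concentration; 1/x and unweighted are selectable). The reported
r is the weighted Pearson correlation under the same weights — whether a
validation report's r is weighted is generally ambiguous, and using the fit
weights is the internally consistent choice. A flat response returns slope
0 and is flagged invalid. Back-calculation inverts the line and reports
negative results with a flag instead of clamping, so that downstream QC
statistics see the actual estimate.

Precision is 100·SD/mean with sample SD; accuracy is 100·mean/nominal.
Accuracy-as-percent-of-nominal and accuracy-as-relative-error differ only
by 100%, and the acceptance windows are equivalent under both conventions.
Windows are treated as closed intervals (a batch exactly on a limit
passes); the LLOQ signal-to-noise screen is strict (S/N > 10 fails at
exactly 10). The `CalibrationSeries` container accepts any ≥ 2 distinct
positive levels so that small numerical fixtures can be fitted; compliance
with the ≥ 6-level validation design is surfaced as a separate `design_ok`
flag rather than a constructor error.

## Network pharmacology

Identifiers are upper-cased and stripped before any set operation, so
`akt1` and `AKT1` are the same target. Degree and closeness centrality are
computed with networkx; closeness uses the Wasserman–Faust component-scaled
convention ((s−1)/(n−1) scaling within a component of size s) so that
disconnected subnetworks remain comparable, with harmonic centrality
available behind a flag. Key targets are the nodes whose degree **and**
closeness both strictly exceed the subnetwork means, ranked by degree then
closeness; when all nodes are equivalent nothing exceeds the mean and the
selection is empty by design. (A selection rule phrased as "median value
higher than the average" is not well defined per node; metric-above-mean on
both centralities is the interpretation implemented.)

Enrichment is the exact hypergeometric upper tail P[X ≥ k] for X ~
HG(N = |universe|, K = pathway∩universe, n = |query|), with BH step-up
q-values across all tested pathways and results sorted by ascending p. The
default universe is the node set of the supplied PPI edge list, overridable.
An EASE-style conservative variant (tail evaluated at k−1) is available
behind a flag for comparability with enrichment servers that use it. The
BH adjustment is implemented directly (vectorised step-up) and
cross-checked against `statsmodels.stats.multitest` in the test suite.
STRING-style confidence scores, when present, can be thresholded; by
default all edges are kept.

## Synthetic data

The PK generator draws, per subject × analyte, individual (ka, ke, scale)
as unit-median lognormal perturbations of the analyte presets with CV 20%
(a typical between-animal variability), evaluates the one-compartment oral
solution C(t) = scale·ka/(ka−ke)·(e^(−ke·t) − e^(−ka·t)) on the 9-point
schedule (0.083, 0.25, 0.5, 1, 2, 4, 8, 12, 24 h), adds proportional (10%
CV) plus additive (0.1 ng/mL SD) Gaussian error, floors negatives at zero
and flags values below the analyte LLOQ as BLQ. True AUC0–∞ = scale/ke and
true t½ = ln2/ke are emitted per subject for recovery studies. Six
subjects and five analytes match the emulated rat study; LLOQs are the
assay's calibration limits (0.5 ng/mL, 0.125 for the EG-like analyte), and
the dose is the 18 g/kg extract equivalent.

The analyte presets fix ke from the reported terminal half-lives and scale
from the reported mean AUC0–∞ values, with ka chosen for a 0.25–0.5 h Tmax.
A one-compartment model cannot simultaneously reproduce the reported Cmax
*and* AUC0–∞ for the fastest-eliminated analyte (a Cmax of that size at
that AUC implies multiphasic disposition), so the presets prioritise AUC
and half-life — the quantities that drive the weighting coefficients and
the recovery criteria — and accept lower Cmax values. Consequently the
generator demonstrates estimator correctness under the stated error model;
it does not demonstrate robustness to multiphasic disposition,
enterohepatic recirculation (double peaks), irregular actual sampling
times, or non-Gaussian assay error, none of which it simulates.

The QC generator draws measured = nominal·bias·(1 + CV·Z). The network
generator plants an intersection of known size, spans it with a path so the
subnetwork of interest is connected, adds Erdős–Rényi edges at density
0.05 (expected degree ≈ 10 in a 200-node universe, comparable to a
medium-confidence PPI export), plants one pathway containing a chosen
fraction of the intersection and draws decoys uniformly. All generators are
pure functions of (config, seed) via `numpy.random.default_rng`.

## Problem sizes

The recovery study uses 200 simulated studies (6,000 profiles); the
planted-pathway experiment uses 100 simulated network universes; the
enumeration oracle for the hypergeometric tail covers every universe up to
N = 12; weight-normalisation checks use 200 random AUC vectors and BH
invariants 1,000 random p-vectors. These sizes give stable medians and
rates while keeping the full suite and the acceptance script each within a
few seconds on one CPU.

## Known limitations

* No compartmental or population (mixed-effects) modelling; NCA only.
* Extravascular parameters only (CL/F, Vz/F); no IV-route or urinary data.
* The analyte-specific dose within a whole-extract dose is generally
  unknown, so CLz/F and Vz/F are extract-equivalent quantities whose
  absolute magnitudes depend on that convention.
* No interpolation across mismatched sampling grids.
* Enrichment ignores gene-set hierarchy (no GO DAG handling) and treats
  pathways independently.
* The pipeline consumes exported target/PPI/pathway files only; it performs
  no live database queries, so results inherit whatever curation the
  exports had.
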