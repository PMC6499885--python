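# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each stage, and what the synthetic scenarios do and do
not establish.

## Adverse-event disproportionality

The reporting odds ratio compares the odds of a target ADR group for an
index drug against the pooled remaining drugs of the same class
(within-class comparator; whole-database comparators are out of scope).
The standard error of log ROR is the Woolf estimator
√(Σ 1/cell), with the CI formed on the log scale (z = 1.96 by default).
Zero cells use the Haldane–Anscombe +0.5 correction on all four cells,
flagged in the result; correction can be disabled, in which case a zero
cell is an error naming the cell.

The dual-risk profile formalizes "outlier in the risk plane": ordinary
least squares of log ROR(group A) on log ROR(group B) across the class,
residuals standardized by the residual SD with n − 2 degrees of freedom,
flag at |standardized residual| > 2 (configurable). Two caveats are
inherent to this construction and documented rather than hidden:

* with few drugs the outlier's own misfit inflates the residual SD, so the
  standardized residual is bounded near √(n − 2); a meaningful flag needs a
  class of roughly ten drugs or more;
* the per-drug flag has a nominal ≈ 5% error rate, so scanning a ~30-drug
  class flags some drug by chance in most datasets. The pipeline's headline
  therefore uses a multiplicity-adjusted threshold (two-sided normal
  quantile at 0.05/n_drugs) and keeps the nominal per-drug profile in the
  stage output file.

## Spectral-count differential testing

The support filter requires summed counts ≥ 2 per condition (a
per-replicate mode exists). The test is an unpaired two-sample t-test,
Welch by default; a pooled-variance option exists. Degenerate rows with
zero variance in both groups get t = 0, p = 1 when means are equal, and
p = 0 when they differ. Benjamini–Hochberg q-values are computed by the
step-up definition (vectorized, exact against a brute-force reference);
rejection is q ≤ α. The downregulated selection follows the study
convention of raw p < α with treated mean below control, ranked by p (ties
by |t| then identifier) and truncated to a presentation limit (default 76);
sensitivity statements refer to the selection rule before truncation.

At n = 3 replicates of Poisson counts the t-test is conservative: null
p-values are slightly super-uniform with mild atoms (false-positive rate
≈ 0.03 at α = 0.05). Calibration checks therefore bound the deviation and
require non-anti-conservatism rather than exact uniformity. Power at the
default effect (mean 20 → 3.3) is limited by the 2–4 df variance estimate,
not by the effect size; a count-model test would be far more powerful but a
plain t-test is the implemented convention.

## Network specificity

Expansion: drop edges with evidence < 2 (evidence semantics — e.g.
literature support count — belong to the input), then add every non-seed
node adjacent to at least two distinct seeds; a node touching one seed
cannot connect anything. Metrics are reported for the induced subgraph and
its largest connected component; the comparison metric defaults to
largest-component edge count, with node counts, edge counts and mean degree
computed alongside.

The null resamples k seeds without replacement from the *measured-protein
universe* (not the whole interactome), expands identically, and uses the
add-one empirical p-value, which is never zero and uniform on a discrete
grid under the null. The hot path runs on a dense boolean adjacency matrix
(fine up to a few thousand nodes; memory grows as n²) and is cross-checked
against a networkx reference implementation in the tests.

## Kinome selectivity

Retention requires residual activity strictly below 50% under at least one
panel drug; the boundary value 50 does not count, and residuals above 100%
(activation) never count as inhibition. The gene-set filter matches
case-folded identifiers; the actin set is built by a case-insensitive
regex over term names of a user-supplied library (GMT format supported),
taking the union of member genes. The activity and gene-set filters
commute, so their order is immaterial.

## AFM elastography

Model: four-sided pyramidal indenter (Bilodeau), F = (tan θ/√2)·E/(1−ν²)·δ²,
with θ = 35° and ν = 0.5 by default; the geometry prefactor is a single
overridable coefficient. Only the approach phase is analyzed. No blunt-tip
correction is applied (no tip radius is modelled); moduli are therefore
*apparent* moduli.

Contact-point detection is a two-stage search: (1) candidate samples are
scored by the whole-curve squared residual of the piecewise model (flat
baseline before the candidate, Hertz law after, with the closed-form
nonnegative E), (2) the winning candidate is refined continuously between
its neighbouring samples by bounded scalar minimization. Candidates are
capped at the force onset — the first sustained rise above the baseline
noise band (median/MAD of the leading fifth, 5σ, three consecutive
samples). The cap matters: without it, curves with non-Hertzian depth
trends (substrate stiffening) are best fitted by sliding the contact deep
into the indented region, which silently cancels the artifact the pointwise
profile is supposed to expose.

The pointwise modulus inverts the force law per sample for δ ≥ 100 nm
(shallower samples amplify noise and contact-point error quadratically).
The substrate flag fires when the least-squares slope of E(δ), estimated
over the deep half of the profile and normalized by the median modulus,
exceeds +20% per µm; the deep-half restriction makes the trend estimate
insensitive to residual contact-point error. Maps report failed pixels as
missing and never interpolate. Group comparison is a one-way ANOVA with
Tukey HSD on per-cell median moduli.

## Dose–response

The 4PL is fitted on log₁₀ concentration, parameterized in log₁₀ EC50 with
bounds two decades beyond the tested range, initialized from the response
extremes and the mid-response crossing. Fits are canonicalized so
top ≥ bottom (flipping asymptotes with h → −h leaves the curve unchanged).
Asymptotes are unconstrained by default with `fix_top`/`fix_bottom`
options. EC50s outside the tested concentration range are flagged as
extrapolated — note that near-flat data can also be "fitted" with an
in-range EC50 and tiny span, so the flag is a necessary, not sufficient,
reliability check. Replicate EC50s are summarized as geometric mean and
geometric SD (sample SD of logs), the right scale for a log-normal
quantity.

## Synthetic scenarios

Generators share one scenario seed through fixed per-stage substreams, so
any stage regenerates identically in isolation. Default scales mirror the
study protocol sizes: 30 drugs × 100 ADR terms with Poisson(40) cell
counts; 2130 proteins × 3+3 replicates at Poisson mean 20 with 76 planted
at ratio 0.165; a 2130-node interactome at mean degree 10 with evidence
1–3 and a 5×-density planted module (internally and toward a pool of
candidate shared intermediates); a 300-kinase × 6-drug panel in which
non-planted kinases are inhibited by zero or ≥ 2 drugs so the planted pair
is the unique single-drug hit by construction; 6×6 grids of 4 µm
indentations (0.1 N/m probe) with 5% multiplicative force noise and a tiny
absolute floor; 8-point dilutions from 0.5 to 50,000 nM with 4 replicates,
5% CV well noise and planted EC50 253 nM.

Deliberate modelling choices: counts are Poisson (a negative-binomial
overdispersion knob exists) since low-replicate spectral counts are
near-Poisson; background drugs share a log-normal risk factor across both
ADR groups so the class falls on the dual-risk correlation line with the
planted drug off it, and the planted drug's group means are scaled so its
*population* ROR equals the requested value exactly; well noise is
proportional (CV), the usual plate-reader error model; the AFM substrate
artifact is a linear relative stiffening with depth. What the generators
do *not* emulate: MedDRA's real ontology depth, between-protein abundance
heterogeneity and peptide-level structure, interactome degree
heterogeneity (scale-free tails), kinome phylogenetic correlation,
cantilever dynamics or adhesion, and plate edge effects. Passing tests
therefore demonstrate correctness of the estimators under clean,
well-specified conditions — not robustness to every artifact of real data.

## Problem sizes in the validation suite

The validation suite and `scripts/acceptance.py` use: 1000 random tables
for oracle agreement, 2000 binomial tables for CI coverage, 200 + 200
scenarios for dual-risk power/calibration, 500 count matrices (10%
planted) for FDR/sensitivity, 1000 p-vectors for BH exactness, 200
repetitions × 500 iterations for network null calibration plus a
1000-iteration planted test, 100 panels for kinome equivalence and 100 for
planted recovery, 36 noiseless + 108 noisy curves for AFM recovery, 100
plates for EC50 recovery, and one full planted + null pipeline pair. These
sizes give binomial standard errors of 1–3% on the reported rates.
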