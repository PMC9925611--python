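# Methods

This note documents the statistical model behind `cctool`, the choices made
where the design was genuinely open, and what the synthetic cohort does and
does not establish about real data.

## Cohort model and analysis matrices

A cohort is two per-subject tables. The clinical table carries group (VPT =
born < 32 gestational weeks; FT = full-term, 37–42 weeks), sex, age at
assessment (months, study range 72–173), gestational age (weeks), IQ on the
mean-100/SD-15 scale, and five raw scores: working-memory span (letter–number
sequencing), processing speed (congruent-condition reaction time, ms),
inhibition (accuracy difference incongruent − congruent), affect recognition
and theory-of-mind totals. The structural table carries 33 measures in a
fixed canonical order: 5 callosal partition volumes (mm³, anterior →
posterior), then 7 CC tract segments (cc1 = rostrum … cc7 = splenium) for FA,
MD, NDI and ODI. MD is stored in 10⁻³ mm²/s so values are O(1) and survive
text serialization without precision tricks; nevertheless CSVs are written
with shortest-round-trip floats and read with the correctly-rounded parser,
so write→load is the identity.

The clinical analysis matrix X fixes the column order (age, gestational age,
IQ, then the five scores). IQ passes through untouched — FCI/GAI are already
age-standardized instruments — as do age and gestational age. The five raw
scores are regressed on age by ordinary least squares *within the analysed
group* and the residuals divided by their sample SD (n−1), giving mean-0/SD-1
columns; each PLSC is fit within one group, so residualization pools no
cross-group information. Regression on age is linear; nothing in the design
motivates a higher order for scores spanning eight years of age. Complete
cases only: subjects with any missing analysed value are dropped at load with
a logged count.

## Normative model and W-scores

LOESS is implemented directly: for each query point the ⌈span·n⌉ nearest
neighbours are weighted with the tricube kernel w = (1−(d/d_max)³)³ and a
local polynomial (degree 2 by default, configurable to 1) fitted by weighted
least squares. Rank-deficient local systems — possible at small spans, where
the farthest neighbour's weight is exactly zero — fall back to the
minimum-norm solution rather than erroring. The degree-1 special case is
verified against statsmodels' lowess to machine precision.

The span is chosen by scipy's bounded Brent minimization over [0.05, 1.0]
(tolerance 10⁻⁴). Two objectives are offered: in-sample SSE (default) and
leave-one-out CV. In-sample SSE is monotone toward the smallest feasible
span — a degree-2 local fit through three points interpolates — so its
minimizer typically sits on the boundary; because the bounded method never
samples the endpoints, the optimizer additionally evaluates both bounds and
returns the best candidate. When the W-score scale is to come from LOESS
residuals (`wscore_basis: loess`), the SSE objective would drive the residual
SD to zero; the LOO-CV objective is the coherent companion there, and a zero
residual SD is a hard error rather than a silent division.

Age bins: the four study bins tile 72–173 months. Bin membership uses
half-open intervals [lo, hi) with the last bin closed and edges
(72, 96.6, 122.1, 148.1, 173), which reproduces the published interval list
exactly (96.5 falls in bin 1, 96.6 in bin 2) and closes the 0.1-month gap a
literal reading would leave. Ages outside all bins are assigned to the
nearest bin with a logged warning, never dropped. Norms are the per-bin FT
sample mean and SD (denominator n−1 — material at bin sizes near 10); a bin
with fewer than 2 FT subjects is an error, fewer than 5 a warning. W-scores
use the bin norms; the LOESS fit is retained for trajectory reporting.
Scoring the FT group against its own norms yields per-bin mean 0 and SD 1
exactly, and W-scores are invariant under any affine transform applied
jointly to a measure's FT and VPT values — both properties are tested.

## PLSC

Both blocks are z-scored column-wise (n−1 denominator) before the
cross-product, making R a correlation matrix; this is what bounds loadings
in [−1, 1] and lets them be read as correlations. The decomposition is the
full SVD of R; saliences are the singular vectors, latent scores the
z-scored blocks projected on them, and loadings the correlations of original
columns with their block's latent scores. Orientation is fixed by making the
largest-magnitude entry of each clinical salience positive (the matching
flip applied to the structural side), so repeated fits are bit-identical.

Permutation test: rows of X are permuted, Y fixed; the k-th observed
singular value is compared per rank against the k-th permuted values without
Procrustes rotation — adequate in the single-dominant-component regime this
pipeline targets, and the simpler convention. p = (1 + count)/(1 + N) never
returns zero and has floor 1/1001 ≈ 0.001 at N = 1000.

Bootstrap: subjects are resampled with replacement jointly in X and Y;
each resample's saliences are sign-aligned to the original by per-component
dot-product flip; loadings are recomputed on the resampled data, so the
bootstrap SD measures sampling variability of the reported statistic itself.
A resample producing a constant column is redrawn (at most 10 retries,
logged). The bootstrap z is the original loading over its bootstrap SD, with
a two-sided normal p; an SD at float-rounding level (< 10⁻¹²) means the
loading is invariant under resampling and is reported as infinite z, p = 0.
Robustness combines p < 0.01 with |loading| ≥ 0.4; both criteria are also
reported separately.

Numerical invariants under test: ΣS² equals ‖R‖²_F and salience blocks are
orthonormal (10⁻⁸); cov(latent_X[k], latent_Y[k]) = S_k; swapping the blocks
swaps the saliences and preserves the spectrum; the decomposition matches
scikit-learn's PLSSVD (an independent implementation) to 10⁻⁸.

## Synthetic cohort: what it emulates, and what it does not

The generator emulates the *derived feature tables* of a VPT/FT
neurodevelopment study, not raw MRI. Defaults reproduce the study design:
39 FT + 65 VPT; ages uniform on 72–173 months; gestational age N(39.83,
1.33²) truncated to [37, 42] weeks (FT) and N(29.59, 1.73²) truncated to
[24, 32) weeks (VPT) — the lower bound is a viability floor. Each structural
measure is a family baseline at a 120-month reference age (typical
along-tract CC profiles: FA 0.58–0.70, MD 0.84–0.92, NDI 0.50–0.58, ODI
0.08–0.14, volumes 410–980 mm³) plus a maturation slope (per month: FA
+5·10⁻⁴, MD −5·10⁻⁴, NDI +8·10⁻⁴, ODI −2·10⁻⁴, volume +1.5), a loading on a
scalar standard-normal latent "maturation" factor, and Gaussian noise
(family SDs 0.02 / 0.03 / 0.03 / 0.01 / 60). The latent factor also drives
IQ (+8), working memory (+1.5) and processing speed (−40 ms), planting one
dominant clinical–structural component. VPT subjects additionally receive a
deviation opposing the maturation direction, proportional to age ×
(32 − GA): per month·week, FA 6·10⁻⁴, MD 4·10⁻⁴, NDI 2.5·10⁻⁴, ODI 3·10⁻⁴,
volume 0.3. Values are clipped to their legal ranges (clipping is logged; at
defaults it touches ≈0.05% of values, in the extreme-prematurity tails).

Two properties sized these defaults, both stated as design conditions of the
generator: the PLSC should recover the planted component decisively at the
study's sample sizes, and the planted W-score-versus-age trends (FA
negative, ODI positive) should carry their signs in ≥95% of seeded cohorts.
The second is the binding constraint: because the deviation is linear in
prematurity, its subject-level scatter grows with the same rate as its mean,
capping the attainable slope signal-to-noise near E[32−GA]/SD(32−GA)-driven
limits. Hence the structural latent couplings are kept near half a noise SD
(so the shared factor does not inflate the W-score scale) and the deviation
rates are deliberately large — a typical FA deficit of ≈0.17 at mean age and
prematurity, stronger than typical empirical VPT–FT differences. The
generator is therefore a *stress cohort* for method validation: passing
tests show the pipeline recovers known structure of this kind and
calibrates its permutation test under the null; they do not show that
real-world effect sizes of this magnitude exist, nor do they validate the
MRI processing that produces real feature tables. Known omissions from the
generative model: no site/scanner effects, no heteroscedastic measurement
error, no missing data, no age–GA correlation by default (a flag plants the
study's negative correlation via a GA-dependent age shift), integer rounding
on count-type instruments only.

`planted_truth` exposes the implied qualitative pattern (loading signs per
variable up to a global component flip; W-trend signs per family) so
recovery tests never hard-code expectations that the spec of the generator
already determines.

## Group-comparison statistics

Welch's unequal-variance t with Satterthwaite df is computed from summary
statistics by the closed-form formulas (the fractional dfs published tables
print are only producible this way) and cross-checked against scipy. The
published age-at-assessment df (82.98) was evidently computed from unrounded
data: the printed 2-dp summaries give 83.00, and the tests assert agreement
at the precision the printed inputs support. The 2×2 chi-square is Pearson's
without continuity correction (the published sex statistic, 0.50, is the
uncorrected value; Yates would give 0.26), delegated to scipy with margin
checks. Pearson correlations report the n−2 df convention.

## Problem sizes in the test suite

The statistical suites run at the sizes that make their claims meaningful on
one CPU in minutes: permutation type-I error over 200 null replicates of 200
permutations at n = 60 (rate asserted within 5% ± 4%); parameter recovery
and W-trend sign recovery over 50 seeded default cohorts with 200
permutations and 500 bootstraps each; the permutation-floor check at the
full 1000 permutations. The acceptance script runs the floor computation at
1000 permutations on the 104-subject pooled cohort.

## Known limitations

* Permutation compares singular values per rank without Procrustes
  alignment; with several comparable singular values, rank swapping can make
  trailing p-values conservative.
* The in-sample SSE span objective is degenerate by construction (see
  above); it is retained as the default for fidelity to the normative
  procedure it reimplements, with LOO-CV as the principled alternative.
* Bin-based norms ignore within-bin age trends; steep trajectories inflate
  σ_norm slightly, shrinking W-scores toward zero.
* The bootstrap p-value assumes approximate normality of the loading's
  bootstrap distribution; for loadings near ±1 the distribution is skewed
  and the two-sided normal tail is approximate.
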