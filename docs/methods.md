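# Methods

This note documents the models, conventions and numerical choices behind
`breathnet`, in the order the pipeline applies them.

## Event-indexed sampling

All series are indexed on respiratory cycles, not wall-clock time: a
breath-by-breath metabolic cart emits exactly one sample per breath, so the
sampling rate *is* the breathing frequency.  A 5-min window at an estimated
rf breaths/min therefore spans `round(rf * 5)` breaths (100 samples at
20 breaths/min, 60 at 12).  Windows are half-open slices `[start, start+n)`
on 0-based breath positions.  Optional Gamma-distributed inter-breath
intervals can be attached by the generator for realism, but no analysis step
consumes them — transfer entropy here is event-indexed by construction.

## Preprocessing

Isolated artifacts (swallowed breaths, mask leaks) are flagged by a Hampel
filter: sample i is an outlier when |x_i − m_i| > t · 1.4826 · c · MAD_i,
where m_i and MAD_i are the median and median absolute deviation of a
centred window (default 11 breaths, shrunk at the edges), 1.4826 maps the
MAD to a normal-consistent sigma, and c = w/(w−0.8) corrects the MAD's
finite-sample downward bias in short windows.  The default threshold t = 3
is therefore a ≈3-sigma rule; on clean autoregressive data it flags well
under 2% of samples.  A window with zero MAD flags any sample that deviates
from the window median at all (so a constant window flags nothing, but a
lone spike among identical values is caught).  Flagged samples are replaced
by linear interpolation over the breath index, with nearest-value extension
at the series ends.  Cleaning never changes series length and never
introduces non-finite values.

## Transfer entropy

With embedding dimension 1 for both histories and prediction horizon λ
(default 5 breaths ≈ 15 s, inside the 5–25 s memory range of
cardiorespiratory series), the plug-in estimator is

    TE(X→Y) = (1/N) Σ_cells n(y⁺, y, x) · log2 [ n(y⁺, y, x) · n(y) / (n(y, x) · n(y⁺, y)) ]

over the N = n − λ triplets (y[t+λ], y[t], x[t]), with 0·log 0 ≡ 0 and the
result clipped at 0.  Conditioning uses the *same* index t for both the
target's and the source's present; units are bits throughout.

Discretisation is equal-frequency (quantile) binning with 6 bins per
variable.  Two deliberate conventions: values tied with a bin edge go to
the lower bin (determinism), and a series with no more distinct values than
bins keeps each distinct value as its own bin, so genuinely discrete inputs
are tabulated exactly — this is what makes the estimator coincide with a
brute-force plug-in tabulation on small discrete alphabets.  Because bin
assignments depend only on ranks, TE is invariant under strictly monotone
transforms of either series; channel units and scales are irrelevant.

An adaptive partition is available as an alternative (`partition=
"adaptive"`): the rank-transformed triplet space is split recursively at
cell medians into octants, a chi-square uniformity statistic (0.95 critical
value, 7 df) decides whether to refine, and marginal cell probabilities are
counted directly from the data.  It handles strongly non-uniform joint
densities better at larger n but is slower and not batched; the quantile
partition is the default everywhere.

The lag scan computes TE at lags 1..5 and reports the plateau onset: the
smallest lag after which every successive relative change
|TE(ℓ+1)−TE(ℓ)|/max(TE(ℓ), 1e−12) stays below 0.10 (else the maximum lag).

## Surrogate significance

The null for a directed pair shuffles the source series uniformly (the
value multiset, hence the marginal, is preserved exactly; the target and
its autocorrelation are untouched) and recomputes TE, 100 times.  The
observed TE is significant when it strictly exceeds the threshold, and
non-significant values are replaced by 0.

The threshold convention matters at this resolution.  For m null values at
the q-th percentile the package uses the ⌈(q/100)(m+1)⌉-th order statistic
— for m = 100, q = 95 the 96th — which is the exact-α permutation rule:
rejecting when the permutation p-value (1 + #{null ≥ obs})/(m + 1) is at
most 0.05, so a true null is flagged with probability exactly 5/101 ≈ 4.95%.
The naive "95th order statistic of 100" alternative rejects 6/101 ≈ 5.94% of
true nulls, i.e. is anti-conservative by construction; the exact rule was
chosen so that the empirical false-positive rate matches the nominal 5%
level, and the null-calibration test verifies this at ±1.5% over 1000
independent pairs.  Whole-series permutation (not block shuffling) is used:
it destroys source autocorrelation, which matches the stated null of "no
lagged information in this source ordering".  No multiple-testing
correction is applied across the 42 pairs; the per-edge level is 5% and the
expected number of false edges in a null network (~2.1) is documented
behavior, not an error.

With quantile binning the surrogate loop is exact but batched: permuting a
source permutes its bin labels, so the 100 null TEs are computed from one
label array via vectorised contingency counting.

## Networks, centrality, similarity

A participant network places each pair's post-surrogate TE in a 7×7
non-negative matrix with zero diagonal, nodes fixed in the order HR, RF,
V̇E, VT, V̇O2, PETO2, PETCO2.  Group networks take the element-wise median
across participants *including* zeroed entries (even counts use the
midpoint), so edges absent in a majority vanish — this is what produces the
sparse group maps under weakened coupling.  Weighted indegree/outdegree are
column/row sums; both sum to the network's total TE.  Rankings sort
descending with ties broken by the fixed channel order.

JSI is the Jaccard index of the binarised edge sets; WJSI is Σ min / Σ max
over the 42 off-diagonal entries.  Two all-empty networks compare as 1
(identical) by convention.  Useful identities: wjsi(a, c·a) = min(c,1)/max(c,1),
and WJSI equals JSI exactly on 0/1-valued matrices.  The nine-comparison
schema (rest–exercise within each condition; condition pairs within each
phase) is fixed in `COMPARISON_SCHEMA`.

## Cohort statistics

The one-way repeated-measures ANOVA uses the classical within-subject
decomposition; partial eta squared is SS_effect/(SS_effect + SS_error).
Mauchly's W and the Greenhouse–Geisser ε come from pingouin; ε deflates
both degrees of freedom only when Mauchly's p < 0.05 (threshold
configurable).  With two levels sphericity holds trivially (ε = 1, test
skipped).  Degenerate inputs (identical columns) return F = 0, η²p = 0
rather than floating-point noise.

Symptom occurrence in a test arm is compared against the control arm by a
goodness-of-fit χ²: expected counts n·p₀ and n·(1−p₀) with p₀ the control
proportion, df = 1.  McNemar's test reports (b−c)²/(b+c) plus the exact
two-sided binomial p when b+c < 25.  Logistic regressions (statsmodels ML
fit) report per-predictor Wald p and odds ratios, the likelihood-ratio p,
and additionally Rao's score test of the global null: at the cohort sizes
this design produces (n = 12) the asymptotic LR test is anti-conservative
(~7% empirical size at nominal 5%) while the score test stays calibrated,
which is why both are carried.  Perfect separation is detected and raised;
zero-variance predictors enter the report with OR 1 and the model reduces
to the informative columns.  VIF, AIC = 2k − 2ll, BIC = k·ln n − 2ll,
McFadden R² = 1 − ll/ll₀ and AUC complete the report.  Correlation matrices
use Pearson r and tie-corrected Kendall τB.  The SpO2/FiO2 (SF) ratio
divides SpO2 in percent by FiO2 as a fraction; the SpO2-on-FiO2 line is
ordinary least squares with the residual SD on n−2 degrees of freedom.

## Synthetic cohort generator

The generator is the package's stand-in for raw study recordings and
defines the conditions under which the pipeline is validated.  Channels
follow a lagged-linear (vector-autoregressive) system in standardised
units, z_j[t] = ar·z_j[t−1] + Σ strength·z_src[t−lag] + ε, mapped to
plausible physiological means/scales (HR 80±4, RF 16±2, V̇E 12±1.5,
VT 0.75±0.08, V̇O2 0.35±0.04, PETO2 100±3, PETCO2 38±1.5); TE is
rank-invariant, so these magnitudes are cosmetic.  Key choices:

- **Couplings live at the analysis horizon.**  Each conceptual link is
  instantiated at lags 4 and 5: physiological couplings act over ~12–15 s,
  and a lag-1-only coupling would be nearly invisible to a lag-5,
  embedding-1 estimator.  Default strengths 0.35–0.45 per lag.
- **Acyclic default wiring.**  Breathing pattern (VT, RF) → ventilation →
  end-tidal gases → HR → V̇O2.  For an acyclic coupling graph the companion
  spectrum reduces to the AR coefficients (0.55), so stationarity holds for
  any strengths in [0, 1]; the spectral radius is still checked and
  non-stationary custom specs are rejected before generation.  Burn-in of
  ≥ 10·max_lag samples precedes every window.
- **Condition and phase effects** are coupling-strength multipliers
  (CTR 1.0/1.0, HY1 0.35/0.8, HY2 0.9/1.0 for rest/exercise), emulating
  globally weakened information transfer under low-grade hypoxia at rest.
  The HY1 exercise phase additionally uses a *rewired* edge set: targets
  rotate downstream within a topological order of the default wiring, so
  the exercise network shares only a minority of links with the rest
  network while remaining acyclic.  This planted decoupling is what the
  similarity analysis must recover as the lowest rest–exercise WJSI.
- **Breathing frequencies** are drawn per recording: rest 15 ± 2.5,
  exercise 25 ± 3 breaths/min (clipped to 8–40), giving ≈75-breath rest and
  ≈125-breath exercise windows at the default 5-min duration.
- **Symptoms** are Bernoulli with logit = intercept + slope · (ground-truth
  total coupling); defaults intercept = logit(1/3) and slope = 0, i.e. a
  one-third prevalence with no true coupling–symptom association, so the
  regression stage's null behaviour can be verified.  Spot SpO2 values are
  generated around a linear SpO2-on-FiO2 response (slope 1.416 %/%,
  intercept 68.83%, noise SD 1.73%).
- **Reproducibility**: one cohort seed expands into per-recording and
  per-draw substreams via `SeedSequence((seed, stage, participant,
  condition, phase))`; any single element can be regenerated in isolation,
  and identical specs and seeds give bitwise-identical cohorts.  Artifact
  injection replaces a chosen fraction of breaths per channel with
  ±k·(1.4826·MAD) spikes and returns the ground-truth indices.

What the generator does *not* emulate: chemoreflex or hypoxic-ventilatory-
response dynamics, nonlinear or non-stationary coupling, continuous SpO2
traces, and measurement quantisation.  Passing tests therefore show that
the pipeline recovers linear lagged couplings and their reorganisation at
realistic sample sizes — not that it would detect arbitrary nonlinear
physiological coupling in real recordings.

## Problem sizes used in validation

The test-suite simulations are sized to the study design they emulate:
5-min windows at 12–30 breaths/min (60–150 samples), 12-participant
cohorts, 100 surrogate shuffles, 1000 independent pairs for null
calibration, 50 cohorts for planted-effect recovery, and 100-seed batches
for detection-power checks.  The analytic TE oracle uses n = 5000 where the
plug-in estimate must approach 1 bit within 0.02.

## Known limitations

Pairwise TE cannot separate redundancy from synergy among multiple sources;
edges through unobserved variables (e.g. SpO2 fluctuations) appear as
direct coupling or as missing flow.  The plug-in estimator's bias grows
quickly with bins³/n, so 6-bin estimates at 60–150 samples are usable only
relative to their surrogate null, never as absolute information rates.
Whole-series shuffling also destroys source autocorrelation, so the null
conflates "no coupling" with "no temporal structure in the source"; block
surrogates are out of scope.  The repeated-measures layer assumes complete
cases and applies no correction across the three ANOVAs.
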