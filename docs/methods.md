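# Methods

## The problem

Subjective image-quality (IQ) ratings drive CT dose-optimization
studies and the validation of automatic IQ metrics, but the standard
instrument — a 5-point Likert scale — is unreliable: raters interpret
the scale points differently, carry systematic offsets, and avoid the
extreme categories. A pairwise-comparison (PC) protocol sidesteps all
three problems by never asking for an absolute score: the observer
repeatedly picks the better of two scans, and a sorting algorithm turns
the answers into a complete ranking. `iqrank` implements that protocol
end-to-end — the comparison-minimizing ranking engine, the agreement
statistics used to evaluate it, a synthetic observer model so the whole
design can be exercised and stress-tested without imaging data, and the
study orchestration and reporting around them.

## Ranking engine

The engine is the Ford-Johnson algorithm (merge-insertion sort), the
comparison sort with the smallest known worst-case comparison count for
the relevant sizes. For n items:

1. form ⌊n/2⌋ pairs and compare within each (odd leftover set aside);
2. recursively rank the winners — the "main chain";
3. binary-insert each loser into the chain. Losers are processed in
   groups whose boundaries are the Jacobsthal numbers 1, 3, 5, 11,
   21, … and in descending index order within a group, which caps every
   binary-search window at 2^t − 1 elements (t comparisons). The
   leftover element, when n is odd, is treated as the final loser
   (index m+1) and inserted in its Jacobsthal group against the whole
   chain.

Worst case: F(n) = Σ_{k=1..n} ⌈log2(3k/4)⌉, so F(50) = 219 versus the
1225 comparisons of a full round robin. The test suite verifies by
exhaustive enumeration (all permutations, n ≤ 8) that the
implementation sorts correctly, never queries the same unordered pair
twice, and that its maximum observed comparison count *equals* F(n) —
i.e. the schedule above is implemented exactly, not merely bounded.

Design choices:

* **Rank direction** — rank 1 = lowest quality, rank n = highest.
* **Side randomization** — which item appears left vs right is drawn
  from the session seed, one bit per issued pair, as a presentation-
  order bias control. It is recorded in the log, so replay is exact.
* **Ties** — none: the protocol is forced-choice by design.
* **Intransitive answers** — accepted silently. Because no redundant
  pair is ever asked, in-session intransitivity is undetectable; the
  ranking is whatever the insertion sequence produces. This is a
  documented limitation of any sorting-based PC protocol, not an error
  state, and the synthetic observers (fresh noise per comparison)
  produce it naturally so downstream statistics are exercised under it.
* **Persistence** — sessions serialize to JSON as
  `{items, seed, records, status}`. The log is the source of truth: on
  load the sorter replays it and verifies each replayed pair against
  the logged one. This survives internal refactors of the sorter at the
  cost of O(comparisons) replay work, which is negligible at n = 50.

## Agreement statistics

Both rating methods are evaluated with the intraclass correlation
coefficient under the two-way random-effects, absolute-agreement model
(McGraw & Wong ICC(A,1) and ICC(A,k)): subjects and raters are both
random samples, and systematic rater offsets count as disagreement.
That convention is what makes the PC/Likert comparison fair — rank data
are offset-free by construction, Likert data are not, and a consistency
ICC would hide exactly that difference.

From the two-way ANOVA mean squares (MSR subjects, MSC raters, MSE
residual) of an n × k complete matrix:

* single measures: (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE));
* average measures: (MSR − MSE) / (MSR + (MSC − MSE)/n).

Interobserver tables use average measures (reliability of the panel
mean, k observers); intraobserver tables use single measures on each
observer's 25×2 repeat matrix. Intraobserver PC entries are the raw
full-session ranks (1–50) of the repeated scans, not re-ranked among
the 25 — the repeat plots and the ICC then describe the same numbers.
Re-ranking is possible upstream if a user prefers it.

Confidence intervals are the F-based ones with a Satterthwaite-
approximated denominator df for the single-measures case; the
average-measures interval is the Spearman-Brown transform of the
single-measures bounds. This is the convention of the major statistical
packages, verified in the tests against the published Shrout-Fleiss
worked example (ICC(A,1) = 0.290, 95% CI 0.019–0.761) and
independently against `pingouin`. Raw estimates may be negative and are
kept; `ICCResult.clamped_display` floors them at 0 for report tables,
since published tables conventionally print "0.000" lower bounds.

Degenerate inputs: a constant matrix (no subject and no residual
variance) has an undefined ICC and raises; a perfect-agreement matrix
returns exactly 1.0 with a degenerate (1, 1) interval; missing cells
are rejected rather than imputed, because silent imputation would
change the estimand of a complete-design study.

**Known limitation.** The single-measures F interval relies on a
Satterthwaite approximation involving the rater mean square, which has
only k−1 degrees of freedom. In Monte-Carlo calibration at n = 50,
k = 6 the interval holds its nominal 95% level when rater variance is
small relative to residual variance (the regime of a trained observer
panel, and the regime the acceptance calibration uses: components
4/0.5/1.5, coverage ≈ 0.95) but undercovers when rater variance is
comparable to residual variance (≈ 0.91 at components 4/1/1, misses
concentrated above the true value). This is a property of the standard
method itself, not of this implementation.

## Synthetic scans and observers

No pixels anywhere: a scan is its metadata plus one latent quality
scalar,

    q = β_current · log(current_pct/100) + β_recon[recon] + u_patient,
    u_patient ~ N(0, σ_patient²).

Defaults: β_current = 2.0 (quality per unit log tube-current fraction;
gives ≈ 1.0 quality units between 60% and 100% current),
β_recon = {FBP: −1.0, IR2: 0.0, IR3: +0.5, IR4: +1.0} (iterative
reconstruction reduces noise, higher strengths smooth more),
σ_patient = 0.5 (habitus/anatomy differences). The resulting pool-wide
latent SD is ≈ 1, which makes the remaining parameters easy to read as
fractions of the quality spread. Log-linearity in dose and additive
reconstruction offsets are the simplest monotone stand-in for the real
(proprietary) noise-insertion reconstruction chain; every coefficient
is config-exposed.

The pool is 17 scans per patient — the original (100% current, IR2)
plus the 16 combinations {60,70,80,90}% × {FBP, IR2, IR3, IR4} — so 30
patients give 510 scans. Two 50-scan study datasets are composed per
study: the 25 included patients' originals plus one non-original per
patient drawn from a per-cell (reconstruction × current) count table.
The high-variation table spreads the 25 non-originals across all
reconstructions and currents; the low-variation table concentrates them
at IR2/90% (18 scans) and IR4 (7 scans), close to the original
operating point. The low-variation cell counts are a documented
approximation — the composition the design calls for is unambiguous
only in its concentration pattern — and both tables can be overridden
in the study config.

Observers are Thurstone Case V: each exposure produces a percept
`scale·q + bias` plus fresh Gaussian noise, so

    P(left preferred) = Φ(scale·(qL − qR) / (√2·σ_compare)),

and a Likert response thresholds the percept at four cut-points. Noise
is per comparison, not per scan; that is what makes simulated choices
intransitive at realistic rates. The default panel has 6 observers with
biases evenly spaced in ±0.5 (some raters systematically score lower),
scale 1, σ_compare = σ_likert = 0.5 (half the latent SD — moderate
noise), and thresholds (−1.0, −0.4, 0.4, 1.0): they span less than the
latent range and the middle interval is widest, reproducing the
central-tendency bias of human raters (most scans get 3 or 4, the
extremes are rare). What the simulation deliberately omits: learning
and fatigue over a session, scan-specific (rather than global)
difficulty, correlated errors between observers, and any real
perceptual model — so passing tests demonstrate the *pipeline's*
statistical behavior under a controlled observer model, not human
performance levels.

## Study pipeline

`run_study` executes the full design: generate the pool (30 patients),
drop 5 random patients (mimicking artifact exclusion), compose the
high- and low-variation datasets over the same 25 remaining patients,
then for every observer × dataset run one PC session and one
randomized-order Likert pass over the identical 50 scans, assemble the
50 × 6 interobserver and 25 × 2 intraobserver matrices, and compute all
ICCs. Every random draw — latent pool, exclusion, composition, observer
percepts, presentation sides, Likert order — comes from a child of
`numpy.random.SeedSequence(master_seed)`, so the entire study is a pure
function of its config. (A `quality_model.seed` set in the config
applies to standalone pool generation; inside the pipeline it is
overridden by the derived child so that `master_seed` alone pins the
study.) Dataset order is high-then-low by default and configurable;
order effects do not exist for simulated observers.

Under the default conditions the pipeline reproduces the qualitative
reliability ordering the protocol is designed to show, verified over
100 replicate studies in the acceptance suite: mean interobserver ICC
is higher for the PC method than for the Likert method on both
datasets, and higher on the high-variation than the low-variation
dataset for both methods. The magnitudes depend on the observer model
and are not meaningful beyond their ordering.

## Reporting

Three diagnostics, each emitted as a CSV table plus a rendered figure
(tables are the record; plots are views): rank-spread boxplots per
dataset (scans sorted by median rank, boxes colored by median Likert
score binned at 0.5, whiskers min/max because Tukey fences are
unstable at k = 6), pairwise and repeat Likert confusion matrices, and
per-observer repeated-rank plots (both median and mean Likert summaries
are included in the tables). CSV output is byte-deterministic for fixed
inputs.

## Problem sizes used in the checks

Exhaustive sorting verification runs all permutations for n ≤ 8
(acceptance) and n ≤ 6 (unit tests); the n = 50 bound is additionally
checked over 1000 random permutations in the acceptance script and 200
in the suite. ICC calibration uses 1000 replicate 50 × 6 matrices
(acceptance) and 200 (unit). The directional study replication uses
100 full studies at the default 30-patient configuration.
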