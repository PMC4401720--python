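# Methods

`saemir` implements a smoking / smoking-cessation miRNA expression analysis
for the small airway epithelium (SAE): differential expression between
nonsmokers, smokers and quitters; classification of smoking-dependent miRNAs
into cessation-reversible vs cessation-persistent; a quartile-based
per-subject signature index; and over-representation statistics for miRNA
categories and target-gene pathways. This note records the model, the
numerical conventions, and the design choices that were genuinely open.

## Statistical model

Each miRNA's log2 intensity is modelled additively as

    y = mu + group + gender + epsilon,    epsilon ~ N(0, sigma^2)

with group in {nonsmoker, smoker_baseline, quitter} and gender as a
covariate, no interaction term. Sums of squares are **Type II**
(SS(group | gender) = RSS(gender-only) − RSS(full)), which for an additive
model is order-invariant in unbalanced designs. Pairwise group comparisons
are **Fisher's LSD** contrasts: t = (mean_a − mean_b)/√(MSE·(1/n_a + 1/n_b))
on the full model's residual df, two-sided, unadjusted. Quitter samples are
deliberately treated as an independent third group — the pairing with the
baseline smokers is validated in the metadata but not modelled — so that
every contrast comes from one coherent model. A paired analysis is out of
scope.

The matrix fit is vectorized: the design matrix is shared by all miRNA rows,
so residual-maker projections are built once (QR) and applied to the whole
matrix. The per-row API wraps the same code path; tests verify agreement
with `statsmodels` `anova_lm(typ=2)` and a from-scratch normal-equations
oracle. If the metadata contains a single gender level the gender term is
dropped (the model then reduces exactly to one-way ANOVA, and the LSD
contrast in a two-group design reduces exactly to the pooled-variance
two-sample t test — both equivalences are tested).

Degenerate inputs: a row with all residuals zero raises an error (no
inference is possible); groups with fewer than 2 samples and aliased
group/gender designs are rejected before fitting.

## Fold-changes and selection gates

Fold-changes are anti-logged differences of group mean log2 intensities,
reported in the signed convention (|FC| ≥ 1; down-regulation as the negative
reciprocal, so −3.8 means 3.8-fold lower). Whether the original array
software derived fold-changes from linear-scale means or anti-logged log2
means is ambiguous; the anti-logged log2-mean convention was chosen because
it matches the log-scale ANOVA that produces the p-values.

Selection uses the published criteria: smoking-dependent if p < 0.01 and
|FC| > 1.5 (smoker vs nonsmoker); cessation-persistent if p < 0.05 and
|FC| > 1.5 (quitter vs nonsmoker). Gates are **strict** inequalities, as the
criteria are printed; for continuous computed values an exact tie has
probability zero, so strictness is inconsequential there. When re-gating the
packaged transcribed tables, whose fold-changes are rounded to one decimal,
`apply_gate(..., fc_inclusive=True)` admits a printed boundary value
(e.g. 1.5): a printed 1.5 stood for an unrounded value that passed the
strict gate, and dropping it would be a rounding artifact, not a
reproduction of the original selection. No multiple-testing correction is
applied in the gates (fidelity to the published raw-p criteria);
Benjamini–Hochberg q-values are reported as an additional informational
column.

## % change (reversibility)

    % change = 100 · (smoker mean − quitter mean) / (smoker mean − nonsmoker mean)

computed from **linear-scale** (anti-logged) group means, since the
statistic describes mean absolute expression levels. 100% is a full return
to the nonsmoker level; values below 0 or above 100 (overshoot) are
legitimate. If the denominator is zero to within relative tolerance 1e-9 the
record is flagged `percent_change_defined = False` rather than aborting the
pipeline. The statistic is invariant to the miRNA's direction (negating all
three means leaves it unchanged; property-tested).

## Quartile index

For each signature miRNA, Q1 and Q3 of nonsmoker expression are interpolated
empirical quantiles (the k-th of n sorted values at probability
(k−1)/(n−1), numpy's default "linear" rule). The per-subject index adds one
point per signature miRNA strictly above Q3 (up-regulated direction) or
strictly below Q1 (down-regulated); boundary ties score zero. The index is
invariant under any strictly monotone transform applied jointly to values
and thresholds (property-tested). The quitter group is scored against the
single nonsmoker-derived threshold set; thresholds are not recomputed per
comparison. At least 4 nonsmoker samples are required.

A calibration subtlety: for a continuous null feature the probability of
exceeding an *estimated* quartile is not exactly 1/4 at small reference
sizes — with n reference values the interpolated Q3 sits at an order
statistic whose exceedance probability is ≈ (n − k + 1)/(n + 1) (0.3 at
n = 9). The index-calibration study therefore uses a large reference sample
(500 train / 500 held-out), where the bias is negligible, to verify the
mean held-out index ≈ signature size / 4.

Group differences in the index use the tie-corrected Kruskal–Wallis H
(chi-square p on groups − 1 df; all-tied data returns H = 0, p = 1 rather
than an error) followed by Dunn's pairwise z tests,
z = (R̄_i − R̄_j)/√((N(N+1)/12 − ΣT/(12(N−1)))·(1/n_i + 1/n_j)), two-sided
normal p, reported unadjusted with a Bonferroni column (no adjustment is
asserted as canonical).

## Enrichment

Over-representation p is the hypergeometric upper tail P[X ≥ k], identical
to the one-sided Fisher exact test, used for both miRNA categories and
target-gene pathways (single implementation, exact equivalence; verified
against exhaustive enumeration for universes ≤ 12). Reported alongside:
count k, percent 100·k/K, and fold-enrichment (k/m)/(K/N), which satisfies
k = fold·(K/N)·m identically. Annotation services are not called; category
and pathway definitions are consumed as generic GMT files. Predicted target
genes are filtered to those expressed in the tissue, RPKM **strictly
greater** than 0.125 (a gene at exactly 0.125 is excluded); the pathway
universe defaults to that expression-filtered gene list.

## Synthetic cohorts

The generator emulates the study conditions: 9 nonsmokers, 10 smokers at
baseline, the same 10 subjects re-sampled as quitters; 1100 miRNAs with 25
planted up and 9 planted down (effect ± `effect_log2` on the log2 scale in
smokers), of which round(12/34 · 34) = 12 stay shifted in quitters
(allocated 9 up / 3 down by largest remainder) and the rest return to
baseline. Noise is Gaussian on the log2 scale (log-normal intensities, the
standard array error model); gender alternates within group (4/5 and 5/5 at
the default sizes) and adds a fixed log2 offset. Quitter values are
regenerated with fresh noise — the paired structure carries no built-in
correlation — unless the optional per-subject random intercept
(`subject_sd_log2`) is enabled. Defaults not fixed by the emulated study
are calibration choices: effect_log2 = 1.5, noise_sd_log2 = 0.5,
gender_effect_log2 = 0.3, per-miRNA baselines ~ N(8, 1) log2 units.

Matching annotation resources plant recoverable positives: one miRNA
category enriched for planted miRNAs at a configurable fold (default 8×
background), one gene pathway from which persistent miRNAs draw half their
predicted targets, random categories/pathways as background, and an RPKM
table straddling the 0.125 floor.

What the generator does **not** emulate: probe-level effects, batch or
spatial array artifacts, correlated miRNA co-regulation, heavy-tailed
noise, and subject-level confounders beyond gender. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own model
assumptions, not robustness to real-array pathologies.

## Study sizes in the validation suite

The simulation studies use 50 replicates/seeds at the full 1100-miRNA,
9/10/10 cohort size (the vectorized fit makes this cheap): null calibration
pools 55,000 null contrasts and checks the p < 0.01 gate rate against
binomial 99% bounds; recovery at effect_log2 = 2.0, noise_sd = 0.5 checks
≥95% selection recovery, ≥90% persistence recovery, the planted pathway
ranked first and a significant index Kruskal–Wallis in ≥90% of seeds.

## Known limitations

- Group-based LSD contrasts ignore the within-subject pairing of baseline
  and quitter samples; a paired test would be more powerful for the
  cessation contrast.
- Raw-p selection gates inflate family-wise error by construction; the
  q-value column is informational only.
- Fold-change convention (log2-mean anti-logged) and the quantile
  interpolation rule are fixed, documented choices among near-equivalent
  conventions; results at thresholds can shift for values near a gate.
- The transcribed tables carry printed precision only (one decimal in FC,
  two significant digits in p), which is why inclusive fold-change gating
  exists for fixture re-analysis.
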