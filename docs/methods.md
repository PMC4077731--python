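# Methods

## Model and assumptions

The pipeline treats a cohort as a log2 expression matrix (genes × samples)
carrying K latent subtypes that differ in mean expression on a small
classifier panel, and asks three questions: how many subtypes the panel
supports (consensus stability), which samples belong to which subtype
(consensus labels, filtered by silhouette), and how subtypes differ
clinically and molecularly (survival, feature enrichment, per-sample GO,
broad CNA).

Consensus clustering assumes that genuine cluster structure is stable
under subsampling: if two samples truly co-segregate, they co-cluster in
most random 80% subsamples. The similarity between samples is the Pearson
correlation of their panel profiles. Because k-means is Euclidean-native,
each sample profile is standardized to zero mean and unit norm before
clustering; on that sphere squared Euclidean distance equals
2·(1 − Pearson r), so Euclidean k-means is monotone-equivalent to
correlation-distance k-means. Final labels are obtained by
complete-linkage hierarchical clustering of 1 − consensus cut at k — the
step where complete linkage belongs in a Monti-style consensus procedure.

The boundary classifier assumes a subgroup is characterized by the
profiles of its member samples rather than a single centroid: a new
sample's average correlation with the members must strictly exceed the
subgroup's *lower boundary* — the minimum within-subgroup pairwise
correlation — for admission, with the maximum average correlation breaking
ties among qualifying subgroups. Samples clearing no boundary are reported
as unassigned rather than forced into the closest subgroup, so a cohort
containing a subtype absent from the training set does not contaminate the
others.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_iter` | 10,000 (500 at desk scale) | subsample runs | reference procedure; 500 runs already give max-entry consensus jitter < 0.1 on the default cohort |
| `subsample_frac` | 0.8 | fraction | reference procedure |
| `n_keep` (panel) | 69 | genes | reference panel size; SD default, MAD selectable |
| CDF `delta_threshold` | 0.15 | relative area gain | see "Numerical choices" |
| silhouette cutoff | s(i) > 0 | — | non-positive width means the sample sits closer to another cluster |
| `min_shared_genes` | 10 | genes | classifier refuses platforms missing most of the panel |
| `min_members` (assignment) | 3 | samples | subgroups attracting fewer validation samples are flagged for exclusion |
| DEG threshold | ±1 | log2 from gene's cohort median | two-fold change, inclusive |
| BH q cutoff | 0.05 | — | per-sample family = all terms × {up, down} |
| prevalence cutoffs | > 0.20 report, ≥ 0.40 highlight | fraction of subgroup | strict > at the reporting cutoff |
| broad-call rule | > 50% of 15 genes with q < 0.25 | — | i.e. ≥ 8 of 15; mean q reported for transparency only |
| `age_floor` | 45 | years | removes the age–survival association before the treated/untreated log-rank |

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` plants: (1) block-structured panel expression — gene g
in subtype c is Normal(mu_g + delta_{g,c}, noise_sd) with delta =
`effect_size` for the panel genes assigned round-robin to c, zero
elsewhere; (2) per-subtype exponential survival with independent
exponential censoring tuned so the expected censored fraction equals
`censor_rate`; (3) binary clinical/molecular flags with per-subtype
Bernoulli rates; (4) gene-set signal — terms of background genes, one per
chosen subtype shifted +2 log2 there; (5) GISTIC-style q-value tracks with
a low-q region planted for chosen subtypes.

Defaults are fixed once as the study conditions: K = 3 subtypes at desk
scale, n = 90 samples, a 69-gene panel among 1,000 genes, effect_size 2.0
at noise_sd 0.5 (signal-to-noise 4), hazards (0.18, 0.66, 0.92)/yr —
median survivals ≈ 3.9, 1.05 and 0.75 years, the long-surviving / bulk /
short-surviving pattern reported for GBM expression subgroups — age means
(38, 49, 49) years with SD 8, censoring 15%, and an IDH1-like/G-CIMP-like
flag pair enriched (0.45 vs 0.05) in the long-surviving subtype.

Not emulated: probe-level noise, batch effects, within-subtype gene–gene
correlation (independence across genes is assumed; the within-subtype
covariance of real panels is unknown), genome-wide CNA correlation
structure, and platform-specific probe dropout beyond the classifier's
pairwise gene dropping. Passing tests therefore demonstrate correctness
of the procedures under the assumed generative model, not robustness to
correlated noise or batch structure in real arrays.

One intrinsic artifact is worth knowing: planting a +2 log2 shift in a
third of the cohort drags the per-gene cohort median up by ≈ 0.35, so the
two-fold-from-median rule can mirror a strongly up-planted term into a
weak "down" enrichment in the other subgroups (prevalence 25–31%, below
the 40% highlight level). This is a property of median-referenced
single-sample enrichment itself, and real cohorts with a dominant
subgroup signature will show it too.

## Numerical choices

- **CDF area and delta.** The area is the exact integral over [0, 1] of
  the empirical CDF of the upper-triangle consensus values; delta(k) is
  the relative gain over k−1 (the raw area at the smallest k). The
  suggested k is the smallest k whose following delta falls below the
  threshold. The default threshold is 0.15: on subsampled consensus the
  area keeps creeping ~5–10% per additional k even past the true k
  (splitting a real cluster produces mid-range consensus mass), while
  gains below the true k exceed 30%, so 0.15 separates the two regimes;
  much smaller thresholds never fire and degenerate to k_max.
- **Consensus denominator.** Pairs never co-subsampled raise an error
  telling the user to increase `n_iter` rather than silently imputing.
- **Silhouette.** Computed on the consensus dissimilarity 1 − M (the
  quantity the labels were derived from); singleton clusters receive
  width 0 and are dropped by the positive-width filter.
- **Ties.** Panel selection breaks variability ties lexicographically by
  gene ID; classifier ties among qualifying subgroups resolve to the
  highest average correlation, then label order; broad-call gene picking
  resolves equidistant genes to the lower coordinate; log-rank handles
  tied event times with the standard hypergeometric variance.
- **Degenerate inputs.** Median centering rejects all-NaN rows; the F
  test returns p = 1 with a warning when both sides have zero variance;
  the G test errors on single-category tables; Kaplan–Meier medians are
  reported as undefined when the curve never reaches 0.5; Cox
  non-convergence propagates as an error.
- **Monte-Carlo goodness of fit.** p = (1 + #{simulated χ² ≥ observed}) /
  (n_sim + 1), the add-one estimator, which cannot return zero and keeps
  the test level-correct for discrete statistics; standardized residuals
  (O−E)/√(E(1−p)) are flagged at |r| > 2.

## Design choices where the design was open

- The variability statistic behind the 69-gene panel is unspecified in
  the source procedure; SD is the default (typical for classifier filters
  of that era) with MAD selectable.
- Whether silhouettes belong on consensus or raw correlation distance is
  ambiguous; consensus distance is used because the filter acts on
  consensus-derived labels.
- The Bonferroni family for feature enrichment is the full
  subgroups × features grid of a run, logged explicitly.
- The per-sample BH family is all terms × both directions; the GO
  universe defaults to measured genes annotated to ≥ 1 term ("all"
  selectable).
- Samples failing every boundary stay "unassigned" instead of being
  forced to the nearest subgroup.
- The cli module is realized as readers/writers plus `run_pipeline`; the
  numbered `analysis/` scripts are the operational interface.

## Problem sizes

Desk-scale runs use n = 90–200 samples, 300–1,000 genes and 150–500
consensus iterations per k; recovery checks run 10–20 independent
cohorts, calibration checks 1,000 null simulations per procedure, and the
enumeration oracles sweep every hypergeometric configuration with
universe ≤ 25 (23,398 cases) and the full 3-cell n = 6 multinomial
support. These sizes were chosen so the whole suite and the acceptance
script each complete in a few minutes on one CPU while leaving the
conclusions seed-stable.

## Known limitations

- The survival-vs-k scan is a blunt model-selection aid: with one
  low-hazard subtype against two similar higher-hazard subtypes, the k = 2
  one-vs-rest contrast (larger groups, Bonferroni factor 1) is expected to
  edge out the best k = 3 pair (×3 correction), so the true k wins the
  scan only ~70–75% of the time under the default hazards. The CDF rule,
  not the scan, is the primary selector.
- Consensus label permutation-equivariance is exact only where consensus
  saturates to 0/1; with a fixed RNG stream, reordering samples reshuffles
  subsample draws, so mid-range consensus entries can differ at the
  subsampling-noise scale.
- The exact G-test's power for the planted flag-enrichment design
  (rates 0.5 vs 0.05, n = 20 per subgroup, Bonferroni family 3) is ≈ 0.94,
  not 1; detection claims are stated accordingly.
- No GO DAG propagation: terms are tested as flat gene sets.
- Broad-call regions must contain ≥ 15 genes; sparser tracks error rather
  than degrade.
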