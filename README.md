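# aktsubtypes

Consensus-clustering subtype discovery and characterization for
AKT-pathway gene expression in glioblastoma (GBM) cohorts.

Bulk expression profiling splits histologically uniform GBM into molecular
subtypes, but generic transcriptome-wide classifiers blur differences in
the one pathway most drug programs target: GFR/PI3K/AKT. This package
implements, end to end, a pathway-focused subtyping analysis for
researchers who want to discover expression subgroups on a curated gene
panel, transfer them to an independent cohort, and ask whether they differ
in survival, clinical/molecular features, per-sample GO biology and broad
copy-number alterations. Because the original microarray cohorts are not
redistributable, a first-class synthetic-cohort generator with planted
subtypes, hazards, gene-set signal and copy-number tracks makes every
stage verifiable at desk scale.

## The method

1. **Preprocessing** — log2 expression is median centered per gene; the
   classifier panel keeps the *n* = 69 most variable candidate pathway
   genes (SD by default, MAD optional).
2. **Consensus k-means discovery** — for each k, k-means is run on many
   random 80% subsamples in correlation geometry (sample profiles
   standardized to zero mean/unit norm so Euclidean k-means orders pairs
   like 1 − Pearson r). The consensus index
   M(i,j) = #(runs clustering i,j together) / #(runs sampling both)
   is accumulated; final labels cut a complete-linkage tree of 1 − M at k.
3. **Model selection** — the empirical CDF of consensus values is
   integrated per k; the relative gain in area ("delta area") flags the k
   past which stability stops improving. A survival scan reports the
   minimum Bonferroni-corrected pairwise log-rank p per k as an orthogonal
   clinical criterion.
4. **Silhouette filter** — samples with silhouette width
   s(i) = (b−a)/max(a,b) ≤ 0 on the consensus dissimilarity are dropped.
5. **Boundary classifier** — each subgroup's lower boundary is the minimum
   within-subgroup pairwise Pearson r on the panel; a new sample joins the
   subgroup with the highest average member correlation among those whose
   boundary it exceeds, else stays unassigned.
6. **Characterization** — one-vs-rest Kaplan–Meier/log-rank and
   age-adjusted Cox survival; F tests (continuous) and likelihood-ratio G
   tests (categorical) with Bonferroni correction; Tukey HSD; a
   Monte-Carlo Pearson goodness-of-fit test with standardized residuals
   for small counts; per-sample hypergeometric GO enrichment on two-fold
   changes from the gene's cohort median with BH correction, summarized as
   per-subgroup term prevalence (> 20% reported, ≥ 40% highlighted); and
   broad copy-number calls from GISTIC-style q-value tracks (15 evenly
   spaced genes, called when > 50% have q < 0.25), plus subgroup-specific
   focal-event filtering.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
cohorts and write their tables under `results/` (regenerated on demand,
not checked in):

```
python analysis/01_simulate_cohorts.py
python analysis/02_discover_subtypes.py
python analysis/03_assign_validation.py
python analysis/04_survival_analysis.py
```

`02_discover_subtypes.py` prints, for the default discovery cohort
(n = 120, three planted subtypes):

```
CDF delta-area rule selects k = 3
 k  cdf_area  delta_area
 2  0.473458    0.473458
 3  0.663215    0.400788
 4  0.719585    0.084996
 5  0.764635    0.062605
silhouette filter kept 120/120 samples
labels vs planted truth: ARI = 1.000
```

— the area under the consensus CDF jumps by 40% going to k = 3 and by
under 10% beyond it, so three subgroups are declared, and they reproduce
the planted labels exactly. `04_survival_analysis.py` then reports the
long-surviving subgroup (median 4.09 years vs 0.90 for the rest, log-rank
p ≈ 2 × 10⁻¹⁰) and shows the subgroup indicator stays significant after
age adjustment in a Cox model — the planted analog of a
favorable-prognosis subtype driven by biology rather than age.

The same stages are available programmatically
(`aktsubtypes.run_pipeline`, driven by a `PipelineConfig` or a YAML file).

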