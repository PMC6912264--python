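# Methods

## The problem

Label-free LC-MS/MS quantification of proteins from a human-tumor xenograft
produces an intensity table with two awkward properties. First, the tissue
mixes proteins of two species — human proteins from the tumor and mouse
proteins from the host stroma — which must be separated before testing.
Second, a large fraction of entries are zero: below-detection measurements
that are missing *not at random* (low-abundance proteins drop out
preferentially). Any differential-expression analysis has to take a stance
on those zeros, and every stance distorts the inference differently —
neglecting them shrinks the per-group sample sizes, while imputing them
fabricates data.

`proteoconsensus` implements a dual-route answer: run the per-protein tests
both ways and call a protein differentially expressed only when the call is
supported by the untouched data or by a stable majority of independently
imputed datasets.

## The pipeline

### Design and ingest

The experiment crosses siRNA treatment (`si-NT` non-targeting control vs.
`si-hVDAC1`) with treatment duration (`short` vs. `long`), giving four
groups with replicate tumors each (three by default). Ingest keeps proteins
of the analyzed organism with at least one unique peptide (both
configurable), drops all-zero rows, and maps zero intensity to "missing" on
the log2 scale with no pseudocount. The same inclusion rule is applied per
organism when the mouse partition is analyzed; whether that is appropriate
is for the analyst to decide — the filter threshold is a parameter.

### QC and sample exclusion

QC computes per-sample signal summaries, a sample dendrogram (Pearson
dissimilarity between samples, complete linkage), and a PCA of the samples
restricted to proteins observed in every sample, centered per protein and
not scaled. Using complete rows only keeps QC independent of the imputation
under test.

Outlying samples are flagged by an explicit rule on the PC1–PC2 plane: each
sample's Euclidean distance from its group's component-wise **median** is
computed, distances are pooled across groups with at least three samples,
and a sample is flagged when its distance exceeds `median + k_mad * MAD`
(default `k_mad = 3`), with the median and normal-consistent MAD taken on
the **square-root** distance scale. Two details are deliberate. A mean
centroid is dragged toward the very outlier being hunted — in a triplicate
group a strong outlier shifts the centroid enough to inflate its clean
neighbours' distances and mask itself — so a robust center is used. And raw
planar distances are right-skewed (roughly Rayleigh under homogeneity), so
a symmetric median±MAD cut in that scale either leaks false flags or misses
real ones; the square root is variance-stabilizing and makes the cut
behave. On synthetic data these choices flag a planted ±3–4 log2-unit
outlier pair in 20/20 seeds while leaving homogeneous data unflagged in
≥95% of seeds.

Flags are advisory. Exclusion happens only when confirmed (config
`qc.confirm_exclude`) or explicitly automated (`qc.auto_exclude`), and
every group must retain at least two samples afterwards — below that the
contrast t-statistic is undefined.

### The six datasets

From the post-exclusion log2 matrix the pipeline builds:

* **dataset 1** — the matrix unchanged; missing entries are neglected
  per protein and per group during testing;
* **datasets 2–6** — five independently seeded imputations. For each
  sample column `s` with observed mean μ_s and (n−1) standard deviation
  σ_s, every missing entry is drawn from
  `Normal(μ_s − downshift·σ_s, (width·σ_s)²)` with defaults
  `width = 0.3`, `downshift = 1.8` — the down-shifted normal used for
  left-censored proteomics imputation (Perseus defaults). Moments are
  per-column because that is the Perseus default; a whole-matrix mode
  exists (`per_column=False`). Imputed values are not truncated at zero
  or at the observed minimum: the defining distribution is the stated
  normal. Seeds follow `base_seed + i`, so each imputed dataset is
  independently reproducible.

Observed entries are bit-identical across all six datasets — an invariant
the tests enforce.

### Per-protein inference

For each protein and each dataset, a one-way ANOVA over the four groups
supplies a pooled error estimate, and two planned contrasts are tested —
treatment effect at short duration and at long duration:

    MSE = Σ_g SS_g / (N_obs − g_obs)        (groups with ≥ 2 observations)
    t   = (x̄_A − x̄_B) / sqrt(MSE · (1/n_A + 1/n_B)),   df = N_obs − g_obs

with a two-sided p from Student's t. Pooling the MSE across all four groups
(rather than a Welch two-group test) is the standard reading of planned
contrasts inside a one-way ANOVA and buys residual degrees of freedom in
the duplicate/triplicate design: with 3+3+2+2 observations the contrast has
6 df instead of 4. A `mse_scope`-style restriction to the contrast pair was
considered and not adopted; with two observed groups only, the statistic
reduces exactly to the classical pooled two-sample t-test (a tested
equivalence).

In dataset 1, a contrast is evaluable only when both of its groups retain
≥ 2 observed values and the residual df is ≥ 1 — the weakest condition
under which t is defined; groups with < 2 observations leave the MSE pool.
Non-evaluable results are marked undefined, not raised. `MSE = 0` with a
nonzero difference is reported as the boundary p = 0.

Fold changes are signed linear: `FC = 2^d` for `d ≥ 0` and `−2^(−d)`
otherwise, where `d` is the difference of log2 group means (a
geometric-mean ratio on the raw scale); |FC| ≥ 1 by construction and
decreases read as "reduced n-fold".

No multiple-testing correction is applied to the per-protein p-values: the
consensus rule is deliberately defined on nominal p-values, and the
FC threshold plus the cross-dataset vote serve as the guard. BH-FDR is
applied only in enrichment.

### Consensus calling

A (protein, contrast) **passes** a dataset when `p < alpha` and
`|FC| > fc_abs`, both strictly (defaults 0.05 and 1.5; values exactly at a
threshold fail). The protein is called differentially expressed when it
passes in dataset 1, or in **more than 3** — i.e. ≥ `min_imputed_pass = 4`
— of the 5 imputed datasets. A dataset-1 result that is not evaluable
counts as not passing; the imputed route remains open.

Two conventions the vote needs and the rule itself does not fix:

* the imputed route fires only when ≥ `min_imputed_pass` of the passing
  imputed datasets agree in direction, so sign-incoherent "DE" calls are
  impossible (such proteins are logged, not called);
* the reported representative FC and p are medians across the imputed
  datasets — robust, and unbiased toward any single fabricated draw — with
  the dataset-1 values carried alongside when defined. Direction is the
  sign of the median log2 difference across passing datasets.

Summaries report per-contrast DE counts, up/down splits, the fraction
down-regulated (undefined when nothing is called), and the union of DE
proteins across contrasts.

### Downstream surfaces

* **Clustering**: DE proteins are standardized per row
  ((x − mean)/sd, sd with n−1; constant rows become zeros and are flagged),
  then clustered with complete linkage on `1 − Pearson r` between protein
  profiles. Rows are sorted by accession before linkage, which makes leaf
  order deterministic and permutation-invariant; zero-variance rows are
  excluded with a log entry.
* **Volcano tables**: per protein, log2 difference, −log10 p and strict
  threshold flags matching the consensus thresholds; plotting is a thin
  matplotlib layer over the table.
* **Enrichment**: one-sided Fisher's exact test per gene set
  (over-representation only), with term membership intersected with the
  background first. The default background is the quantified-protein
  universe that survived ingest — the tested list was drawn from it, and a
  genome-wide background would overstate enrichment — but any background
  set can be passed. Protein-to-gene mapping is collapsed to unique
  symbols before testing. BH step-up q-values; the reporting filter keeps
  terms with `q < 0.05` and strictly more than 4 DE members.

## The synthetic-data generator

Real data for this design are not bundled, so the generator emulates the
statistical structure every stage assumes, and ground truth rides along for
recovery tests.

* Intensities are log-normal: per-protein baselines
  `Normal(baseline_log2_mean = 25, protein_level_sd = 2.5)`, within-group
  replicate noise `baseline_log2_sd = 0.5` log2 units — representative of
  label-free protein-level intensity tables.
* Composition: 1,845 human proteins and 400 mouse proteins by default,
  triplicates in each of the four groups.
* Effects: a `de_fraction` (default 6%) of proteins per contrast carry a
  true effect with magnitude uniform on `effect_log2_range = (0.8, 3.0)`
  and random sign, applied to the si-hVDAC1 group of that duration only.
* Missingness is **mechanistic, not the imputation model**: each entry
  drops out with probability `sigmoid(steepness · (midpoint − x))`
  (defaults midpoint 21.5, steepness 1.0 per log2 unit, ≈ 10–12% zeros).
  Testing a down-shifted-normal imputation against data censored by a
  different mechanism avoids circular validation.
* One designated replicate (replicate 1 of each long-duration group) can
  be shifted by `outlier_sample_shift` log2 units to plant the exceptional
  sample pair that exercises the QC-exclusion path.
* Gene sets: terms drawn from the simulated gene universe; "enriched"
  terms oversample true-DE genes at a configurable odds ratio recorded in
  the term description.

What the generator does **not** emulate: peptide-level evidence and shared
peptides between species, between-sample normalization artifacts, batch
effects, correlated missingness within a sample, or heavy-tailed intensity
noise. Passing tests therefore demonstrate that the pipeline's logic and
statistics behave as specified under its own assumptions — not that those
assumptions hold for any particular instrument or cohort.

## Numerical and reproducibility choices

* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  the CLI derives one seed per stage from a single global seed via SHA-256,
  so partial reruns reproduce exactly. Identical config + seed gives
  byte-identical outputs (tested).
* Standard deviations use the n−1 denominator throughout.
* Degenerate inputs: columns with < 2 observed values cannot be imputed
  (error naming the sample); groups reduced below 2 samples by exclusion
  are a hard error; PCA k is reduced with a warning when complete rows are
  scarce; the sample dendrogram is skipped below 2 complete rows.
* Problem sizes in the test-and-verification layer (2,000-protein null
  calibration over 3 seeds, 10^4-cell imputation moments, 20-seed outlier
  recovery, 300-protein effect-recovery grids) are chosen so Monte-Carlo
  error is small relative to the tolerances being checked while the whole
  suite runs in seconds.

## Known limitations

* The consensus rule is a vote, not Rubin's-rules pooling; its sampling
  behavior under heavy missingness is characterized only empirically here.
* No moderated (empirical-Bayes) variance shrinkage; with duplicate groups
  the per-protein variance estimate is noisy, which the pooled four-group
  MSE only partly mitigates.
* No between-sample normalization is applied by default; a median
  alignment of sample log2 distributions is available as an opt-in
  pre-step (`qc.normalize`). Otherwise the pipeline assumes the input
  table is already on a comparable scale across samples.
* Organism assignment and unique-peptide counts are taken from the input
  annotations as given; peptide evidence is never re-examined.
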