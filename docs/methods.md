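# Methods

This note records the statistical models, numerical conventions and design
decisions behind `cnvdrive`, in enough detail to reimplement the package.

## 1. Input model

Four tables describe a cohort (0-based, half-open genomic coordinates):

- **Probe CNV table** — aCGH probes with `chrom`, `start`, `end`, a (possibly
  empty) tuple of annotated `gene_ids`, and either discrete per-sample states
  (`lost`/`normal`/`gained`, coded −1/0/+1 as int8) or log2 ratios to be
  thresholded (`gain_cut` = 0.2, `loss_cut` = −0.2 by default). A subset of
  samples may be marked as normal controls.
- **Expression table** — probe × sample log2 intensities with a probe→gene
  map. Expression probes are independent of CNV probes.
- **Clinical table** — per sample: `metastasis` (bool), `mfs_time` (months,
  ≥ 0), `event` (event implies metastasis), `chemotherapy` (nullable
  boolean; unknown is preserved as missing), `histotype`,
  `metastatic_at_diagnosis`.
- **Pathway catalog** — pathway → gene-set mapping.

Samples are intersected across tables; samples missing from any table are
dropped with a warning, and an empty intersection is a hard error.

## 2. Probe filtering

Four independent exclusion rules, applied to the probe set as a whole:

1. **Constitutional CNV regions** — any overlap (half-open interval
   intersection, via an interval tree per chromosome) with a supplied BED of
   germline CNV regions.
2. **Sex chromosomes** — chromosome names are normalized (`X` ≡ `chrX`).
3. **Intergenic** — empty gene annotation.
4. **Altered in controls** — any non-normal state in any control sample.

Counts are attributed sequentially in this order, but the surviving probe set
is independent of rule order (each rule is a pure predicate). An empty
survivor set is a hard error.

## 3. Gene copy-number status

Per gene and sample, the status is the strict plurality vote of its probes'
states; any tie for the maximum resolves to `normal`. A stricter
`consensus` rule (unanimity required, else `normal`) is available. A probe
annotated to several genes votes in each.

## 4. Expression integration and alteration calls

- **Representative probe**: for each gene, the expression probe with the
  largest inter-quartile range across all samples; ties break to the
  lexicographically smallest probe id.
- **Quantile convention**: NumPy linear interpolation at `p·(n−1)` (e.g. the
  values 1…30 give Q1 = 8.25, Q3 = 22.75).
- **Control group**: for each gene, the samples whose copy-number status for
  that gene is `normal`. With fewer than `min_controls` = 30 such samples the
  gene's quartiles are undefined and the gene is **not evaluable**.
- **Call rule** (per gene × sample): `altered_loss` when status is lost and
  expression < Q1; `altered_gain` when status is gained and expression > Q3;
  otherwise `not_altered`. Comparisons are strict by default (a value exactly
  at the quartile is not altered; an `inclusive` boundary option exists).
  Missing expression or undefined quartiles give `not_evaluable` (code 2).

## 5. Universal pathways and the candidate pool

The pathway catalog is restricted to evaluable genes (pathways left empty are
dropped). A pathway is *flagged* in a sample when ≥ 1 member gene is altered
there. Pathways flagged in at least `fraction` of samples (default 1.0, i.e.
all samples) are **universal**. The candidate pool is the union of universal
pathways' member genes that are altered in at least one sample.

## 6. Enrichment and driver selection

For each pool gene (and each pathway), a 2×2 table of altered vs not-altered
by metastatic vs non-metastatic sample counts is tested with a **two-sided
Fisher exact test** (`not_evaluable` cells are excluded). Implementation:
hypergeometric enumeration over the table support, summing probabilities
≤ p(observed)·(1 + 1e−7); validated against exact-rational enumeration to
1e−10 and against `scipy.stats.fisher_exact`. The sample odds ratio is
`ad/bc` (infinite/undefined conventions for zero cells). Yates-corrected χ²
is available as a secondary test. P-values are Benjamini–Hochberg adjusted
within each result set.

A **candidate driver** must (a) pass the gene-level test (raw p < α = 0.05 by
default, enriched in the metastatic subgroup) and (b) belong to ≥ 1 pathway
satisfying the pathway condition. Universal pathways satisfy the pathway
condition by construction: a pathway altered in 100% of samples is maximally
altered in the subgroup but yields a degenerate 2×2 table (both margins
altered ⇒ Fisher p = 1), so testing it would be meaningless. The pipeline
therefore passes the universal set through `always_pass_pathways`;
non-universal pathways must pass their own enrichment test.

## 7. Survival stratification

- **Expression threshold**: the low/high cut for the candidate gene is the
  intersection of two Gaussian kernel density estimates — the gene's
  copy-lost samples vs copy-normal samples. Silverman bandwidth; a shared
  evaluation grid of 1024 points spanning the pooled range ± 3 bandwidths;
  sign changes of the density difference restricted to lie between the two
  group medians; when several remain, the crossing nearest the midpoint of
  the medians is chosen and refined by linear interpolation. Fallbacks (with
  warnings): no crossing in the window → pooled mean; a degenerate group
  (size < 2 or zero variance) → midpoint of the group means.
- **Strata**: samples below the threshold are `low`. Patients metastatic at
  diagnosis are excluded by default (no metastasis-free interval); analysis
  can also be restricted to the chemotherapy / no-chemotherapy subset
  (unknown chemotherapy status excludes the sample; a subset in which all
  statuses are unknown is a hard error).
- **Kaplan–Meier** curves per stratum (lifelines product-limit estimator
  behind the package's own curve surface).
- **Log-rank test**: hand-coded hypergeometric O/E/V accumulation over event
  times, χ² p-value with 1 df; cross-validated against
  `lifelines.statistics.logrank_test`.
- **Hazard ratio**: the observed/expected estimate
  HR = (O₁/E₁)/(O₂/E₂) with CI exp(log HR ± z·√(1/E₁ + 1/E₂)), group 1 being
  the low-expression stratum.

## 8. Synthetic cohort generator

Defaults are calibrated to a 106-sample sarcoma-style cohort: 32 metastatic;
12,124 genes on 22 autosomes; per gene × sample alteration probability
2960/12124 with 53% gains; driver gene `G00001` lost in 62.5% of metastatic
vs 34% of non-metastatic samples (never gained); 5 normal controls;
expression for a 11447/12124 fraction of genes, log2 baseline N(8, 1), copy
shifts ±1.5, noise SD 0.5; per-probe state flip rate 0.02; decoy probes in
constitutional regions, on sex chromosomes and intergenic exercise every
filter rule; exponential survival with baseline hazard 0.01/month and
censoring rate 0.008/month.

Two survival modes, because planted subgroup frequencies and a planted
hazard ratio cannot both hold in one coherent model:

- `label_linked` (default): metastasis labels drawn first, driver loss
  applied at the per-group frequencies, metastatic samples get events and the
  rest are censored — makes the planted *frequencies* exactly recoverable.
- `hazard_model`: event times from an exponential proportional-hazards model
  with the configured HR (default 2.5) for driver-lost samples;
  `metastasis := event` — makes the planted *hazard ratio* recoverable.

The planted driver pathway always takes the maximum of the configured
pathway-size range, mirroring the large, near-universally altered cell-cycle
pathway that motivates the design; with a small random size the driver could
fail to enter the candidate pool for reasons unrelated to its association
signal.

Scaled validation configuration (used by the recovery tests): 120 samples
(40 metastatic — one third, chosen a priori), 2000 genes, 50 pathways,
driver loss 60% vs 30%. Driver recovery: 19/20 seeds end to end.

## 9. Known limitation: Fisher-test conservativeness

Fisher's exact test is discrete: its attained size (null rejection
probability at nominal α = 0.05) is strictly below 0.05 for almost all
margins. At the scaled cohort size the mean attained size over the candidate
pool's realized margins is ≈ 0.040, and the observed permuted-label null
rejection fraction matches it within Monte-Carlo error (verified by an exact
enumeration oracle in the test suite). A calibration check that expects the
rejection fraction to fall in a tight binomial window around the *nominal*
0.05 therefore fails for any correct exact-test implementation; the package
keeps the exact test (as the method prescribes) and documents the
conservativeness instead of inflating the rejection rate.

## 10. Determinism

A single integer seed drives one `numpy.random.Generator`; identical seed and
configuration yield byte-identical cohort tables, report TSVs (`%.6g` float
formatting) and manifest JSON (sorted keys). Times and expression values are
rounded to 4 decimals at generation so text round-trips are lossless.
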