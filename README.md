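# cnvdrive

Integrative copy-number + expression driver-gene discovery for sarcoma-like
tumor cohorts.

`cnvdrive` implements a pipeline that combines array-CGH copy-number calls
with expression microarray data to nominate candidate driver genes whose
copy-number alteration is (a) functionally confirmed by a concordant
expression change, (b) part of a pathway altered across the whole cohort, and
(c) enriched in the metastatic subgroup — and then tests the survival impact
of the top candidate by stratifying patients on its expression.

## The method

1. **Probe filtering** — aCGH probes are removed when they overlap
   constitutional (germline) CNV regions, lie on sex chromosomes, map to no
   gene, or are altered in normal-control samples. Four independent exclusion
   rules; the surviving set is order-insensitive.
2. **Gene copy-number status** — each gene gets a per-sample status in
   {lost, normal, gained} by majority vote over its probes; ties resolve to
   normal (a `consensus` rule requiring unanimity is also available).
3. **Expression integration** — one representative expression probe per gene
   (maximum inter-quartile range across samples). For each gene, the samples
   that are copy-*normal* for that gene form its control group; their
   expression Q1/Q3 define the normal range (at least 30 controls, else the
   gene is not evaluable). A gene is called **altered** in a sample when it is
   lost *and* expressed below Q1, or gained *and* expressed above Q3 —
   copy-number change functionally confirmed by expression.
4. **Universal pathways** — a pathway is flagged in a sample when at least one
   member gene is altered. Pathways flagged in every sample (fraction
   configurable) are "universal"; their altered member genes form the
   candidate pool.
5. **Subgroup enrichment** — per gene and per pathway, a two-sided Fisher
   exact test of alteration frequency in metastatic vs non-metastatic
   samples, with Benjamini–Hochberg adjustment. A candidate driver must pass
   the gene test *and* belong to at least one pathway satisfying the pathway
   condition (universal pathways satisfy it by construction; see
   `docs/methods.md`).
6. **Survival stratification** — patients are split into low/high expression
   of the candidate driver at the intersection of the kernel density
   estimates of its copy-lost vs copy-normal samples; metastasis-free
   survival is compared with Kaplan–Meier curves, the log-rank test and an
   observed/expected hazard ratio.

A calibrated synthetic-cohort generator (`cnvdrive.simulate`) produces
cohorts with a planted driver gene, planted subgroup loss frequencies or a
planted proportional-hazards effect, decoy probes exercising every filter
rule, and fully seeded determinism — used for all validation.

## Worked example

Simulate a 120-sample cohort with a driver gene deleted-and-underexpressed in
60% of metastatic vs 30% of non-metastatic samples, then run the full
analysis:

```python
import warnings
from cnvdrive.simulate import SimulationConfig, simulate_cohort
from cnvdrive.pipeline import PipelineParams, analyze_bundle

cfg = SimulationConfig(seed=0, n_samples=120, n_metastatic=40, n_genes=2000,
                       n_pathways=50, driver_loss_freq_metastatic=0.6,
                       driver_loss_freq_nonmetastatic=0.3)
sim = simulate_cohort(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = analyze_bundle(sim.bundle, PipelineParams(),
                         constitutional_regions=sim.constitutional_regions)
print("planted driver:", sim.truth.driver_gene)
print(res.drivers.head(3).to_string())
sa = res.survival
print(f"threshold {sa.threshold.threshold:.3f}  logrank p {sa.logrank.p:.4g}  "
      f"HR {sa.logrank.hazard_ratio:.2f}")
```

Output:

```
planted driver: G00001
        alteration_type  p_fisher  p_adjusted  odds_ratio supporting_pathways
gene_id
G00001             loss  0.000734    0.572011    3.954545               P0001
G00908             loss  0.002244    0.764158    3.920635               P0049
G01894             loss  0.006779    1.000000    3.769231               P0045
threshold 6.076  logrank p 0.009639  HR 2.25
```

The planted driver is recovered as the top-ranked candidate (loss-type,
Fisher p = 7.3e-4), and stratifying patients at the density-intersection
expression threshold (6.08 log2 units) yields a significantly worse
metastasis-free survival for the low-expression stratum (log-rank
p = 0.0096, O/E hazard ratio 2.25).

The same analysis from the command line:

```bash
cnvdrive run --simulate --seed 0 --out out/          # report TSVs + manifest.json
cnvdrive simulate --seed 0 --out-dir cohort/         # write the input tables only
cnvdrive run --config analysis.yaml --out out/       # run on real input files
```

`analysis.yaml` holds analysis parameters (any `PipelineParams` field) and an
`inputs:` mapping with paths for `cnv`, `expression`, `clinical`, `pathways`
and optionally `controls` and `constitutional`.

## Reproduction

All randomness is seed-driven; identical seed and configuration give
byte-identical outputs.

```bash
pytest -q                                                  # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` simulates the default calibrated cohort (106 samples,
12,124 genes), runs the complete pipeline and writes the headline quantities
(alteration load, gain fraction, universal-pathway and candidate-driver
counts, expression threshold, log-rank statistics, hazard-ratio recovery) as
JSON. Runtime is under 10 seconds on one CPU.

## Layout

- `src/cnvdrive/io.py` — table schemas, readers/writers, report output
- `src/cnvdrive/cnv.py` — probe filtering and gene-status aggregation
- `src/cnvdrive/expression.py` — representative probes, control quartiles, alteration calls
- `src/cnvdrive/pathways.py` — pathway flags and universal-pathway selection
- `src/cnvdrive/enrichment.py` — Fisher/χ² tests, BH adjustment, driver selection
- `src/cnvdrive/survival.py` — density threshold, Kaplan–Meier, log-rank, O/E hazard ratio
- `src/cnvdrive/simulate.py` — calibrated synthetic cohort generator
- `src/cnvdrive/pipeline.py` — end-to-end orchestration and report writing
- `src/cnvdrive/cli.py` — `cnvdrive` command
- `docs/methods.md` — methods note: models, conventions, design decisions
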