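"""End-to-end orchestration: filter → status → integrate → pathways →
enrich → drivers → threshold → survival.

``analyze_bundle`` runs the whole analysis in memory on a
:class:`~cnvdrive.io.CohortBundle`; ``run_all`` wraps it with file loading
(or simulation), report TSVs and a JSON manifest recording the configuration,
seed, input digests and per-stage counts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cnv import (
    aggregate_gene_status,
    filter_probes,
    threshold_logratio_probes,
)
from .enrichment import (
    gene_subgroup_enrichment,
    pathway_subgroup_enrichment,
    select_candidate_drivers,
)
from .expression import (
    alteration_load,
    call_alterations,
    compute_control_stats,
    select_representative_probes,
)
from .io import (
    CohortBundle,
    file_sha256,
    load_cohort,
    read_bed_regions,
    write_report,
)
from .pathways import (
    flag_pathways,
    genes_in_universal_pathways,
    restrict_catalog,
    select_universal_pathways,
)
from .survival import mfs_analysis

logger = logging.getLogger("cnvdrive")


class PipelineError(RuntimeError):
    """Raised when the pipeline cannot be run as configured."""


@dataclass
class PipelineParams:
    """All analysis thresholds in one place (YAML-serializable)."""

    gain_cut: float = 0.2
    loss_cut: float = -0.2
    sex_chroms: tuple[str, ...] = ("chrX", "chrY")
    tie_rule: str = "normal"
    min_controls: int = 30
    quantile_convention: str = "linear"  # p·(n−1) positional interpolation
    boundary: str = "strict"
    fraction: float = 1.0
    alpha: float = 0.05
    adjust: str = "none"  # none | bh
    yates: bool = False
    dichotomize_method: str = "density_intersection"
    fixed_threshold: float | None = None
    kde_bandwidth: str = "silverman"
    kde_grid_size: int = 1024
    subset: str = "all"
    exclude_metastatic_at_diagnosis: bool = True
    survival_gene: str | None = None  # default: top candidate driver

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        params = cls(**known)
        if params.sex_chroms:
            params.sex_chroms = tuple(params.sex_chroms)
        return params


@dataclass
class PipelineResult:
    filter_counts: dict
    gene_status: "pd.DataFrame"
    alterations: "pd.DataFrame"
    load: dict
    universal_pathways: list[str]
    candidate_pool: frozenset
    gene_enrichment: "pd.DataFrame"
    pathway_enrichment: "pd.DataFrame"
    drivers: "pd.DataFrame"
    survival: object | None
    counts: dict = field(default_factory=dict)


def analyze_bundle(
    bundle: CohortBundle,
    params: PipelineParams | None = None,
    constitutional_regions: "pd.DataFrame | None" = None,
) -> PipelineResult:
    """Run the full driver-discovery analysis on an in-memory cohort."""
    params = params or PipelineParams()
    t0 = time.time()

    cnv = bundle.cnv
    if not cnv.is_discrete:
        cnv = threshold_logratio_probes(cnv, params.gain_cut, params.loss_cut)
    cnv, fcounts = filter_probes(
        cnv,
        constitutional_regions=constitutional_regions,
        sex_chroms=params.sex_chroms,
    )
    # controls served the probe filter; the analysis runs on tumors only
    cnv_tumors = cnv.subset_samples(cnv.tumor_samples)
    status = aggregate_gene_status(cnv_tumors, tie_rule=params.tie_rule)
    logger.info("gene status: %d genes × %d samples (%.1fs)",
                *status.status.shape, time.time() - t0)

    rep = select_representative_probes(bundle.expr)
    stats = compute_control_stats(rep, status, min_controls=params.min_controls)
    alt = call_alterations(status, rep, stats, boundary=params.boundary)
    load = alteration_load(alt)

    catalog, dropped_pathways = restrict_catalog(bundle.pathways, alt)
    pam = flag_pathways(catalog, alt)
    universal = select_universal_pathways(pam, fraction=params.fraction)
    pool = genes_in_universal_pathways(universal, catalog, alt)

    subgroup = bundle.clinical.data["metastasis"].astype(bool)
    gene_enr = gene_subgroup_enrichment(
        alt, subgroup, candidate_pool=pool, with_chi2=True, yates=params.yates
    )
    path_enr = pathway_subgroup_enrichment(pam, subgroup)
    drivers = select_candidate_drivers(
        gene_enr, path_enr, catalog,
        alpha=params.alpha,
        use_adjusted=params.adjust == "bh",
        always_pass_pathways=frozenset(universal),
    )

    survival = None
    surv_gene = params.survival_gene
    if surv_gene is None and len(drivers):
        surv_gene = drivers.index[0]
    if surv_gene is not None:
        try:
            survival = mfs_analysis(
                bundle, surv_gene, rep, status,
                method=params.dichotomize_method,
                threshold=params.fixed_threshold,
                subset=params.subset,
                exclude_metastatic_at_diagnosis=params.exclude_metastatic_at_diagnosis,
                bandwidth_rule=params.kde_bandwidth,
                grid_size=params.kde_grid_size,
            )
        except Exception as exc:  # noqa: BLE001 — survival is best-effort
            logger.warning("survival analysis skipped for %s: %s", surv_gene, exc)

    counts = {
        "probes_kept": int(len(cnv.probes)),
        "probes_removed": fcounts.as_dict(),
        "genes_with_status": int(status.status.shape[0]),
        "evaluable_genes": load["n_evaluable_genes"],
        "mean_alteration_load": load["mean_load"],
        "gain_fraction": load["gain_fraction"],
        "pathways_retained": len(catalog.gene_sets),
        "pathways_dropped": dropped_pathways,
        "universal_pathways": len(universal),
        "candidate_pool": len(pool),
        "enriched_genes": int(
            (
                (gene_enr["p_fisher"] < params.alpha)
                & (gene_enr["direction"] == "enriched_in_subgroup")
            ).sum()
        ),
        "candidate_drivers": int(len(drivers)),
    }
    logger.info("analysis complete in %.1fs: %s", time.time() - t0, counts)
    return PipelineResult(
        filter_counts=fcounts.as_dict(),
        gene_status=status.to_labels(),
        alterations=alt.to_labels(),
        load=load,
        universal_pathways=universal,
        candidate_pool=pool,
        gene_enrichment=gene_enr,
        pathway_enrichment=path_enr,
        drivers=drivers,
        survival=survival,
        counts=counts,
    )


def run_all(
    config_path: str | Path | None = None,
    out_dir: str | Path = "cnvdrive_out",
    simulate: bool = False,
    seed: int | None = None,
    inputs: dict | None = None,
    params: PipelineParams | None = None,
) -> Path:
    """File-level entry point: load or simulate, analyze, write the report.

    ``inputs`` maps cnv/expression/clinical/pathways (and optionally
    controls/constitutional) to paths; with ``simulate`` the synthetic
    generator provides the cohort instead.  Returns the report directory.
    """
    from .simulate import SimulationConfig, simulate_cohort

    raw_cfg: dict = {}
    if config_path is not None:
        raw_cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    if params is None:
        params = PipelineParams(
            **{k: v for k, v in raw_cfg.items()
               if k in PipelineParams.__dataclass_fields__}
        )
    input_digests = {}
    constitutional = None
    if simulate:
        sim_cfg_raw = {
            k: v for k, v in raw_cfg.get("simulation", {}).items()
            if k in SimulationConfig.__dataclass_fields__
        }
        if seed is not None:
            sim_cfg_raw["seed"] = seed
        sim_cfg = SimulationConfig(**sim_cfg_raw)
        sim = simulate_cohort(sim_cfg)
        bundle = sim.bundle
        constitutional = sim.constitutional_regions
        seed = sim_cfg.seed
    else:
        inputs = inputs or raw_cfg.get("inputs", {})
        for key in ("cnv", "expression", "clinical", "pathways"):
            if key not in inputs:
                raise PipelineError(f"missing input path: {key!r}")
        bundle = load_cohort(
            inputs["cnv"], inputs["expression"], inputs["clinical"],
            inputs["pathways"], controls_path=inputs.get("controls"),
        )
        if inputs.get("constitutional"):
            constitutional = read_bed_regions(inputs["constitutional"])
        input_digests = {k: file_sha256(v) for k, v in inputs.items() if v}

    result = analyze_bundle(bundle, params, constitutional_regions=constitutional)

    report: dict[str, object] = {
        "version": __version__,
        "seed": seed,
        "params": asdict(params),
        "input_digests": input_digests,
        "stage_counts": result.counts,
        "universal_pathway_ids": result.universal_pathways,
        "gene_status": result.gene_status,
        "alterations": result.alterations,
        "gene_enrichment": result.gene_enrichment,
        "pathway_enrichment": result.pathway_enrichment,
        "drivers": result.drivers,
    }
    if result.survival is not None:
        sa = result.survival
        curves = []
        for label, c in sa.curves.items():
            curves.append(pd.DataFrame({
                "stratum": label, "time": c.times, "at_risk": c.at_risk,
                "events": c.events, "survival": c.survival,
            }))
        report["survival_curves"] = pd.concat(curves, ignore_index=True)
        report["survival"] = {
            "gene": sa.gene_id,
            "threshold": sa.threshold.threshold,
            "threshold_method": sa.threshold.method,
            "group_sizes": list(sa.threshold.group_sizes),
            "logrank_statistic": sa.logrank.statistic,
            "logrank_p": sa.logrank.p,
            "hazard_ratio": sa.logrank.hazard_ratio,
            "hr_ci": list(sa.logrank.hr_ci),
        }
    paths = write_report(report, out_dir)
    logger.info("report written to %s (%d files)", out_dir, len(paths))
    return Path(out_dir)
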