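"""Probe filtering and gene-level copy-number status calling.

Probes are excluded, in order, when they (1) overlap a referenced
constitutional copy-number-variation region, (2) target a sex chromosome,
(3) are not localized in any gene, or (4) are altered in at least one control
sample.  Each surviving gene then receives one status per sample — lost,
normal or gained — by a majority vote over its probes, with ties resolved
conservatively to normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ProbeCnvTable, normalize_chrom

DEFAULT_SEX_CHROMS = ("chrX", "chrY")


class CnvStatusError(ValueError):
    pass


def threshold_logratio_probes(
    table: ProbeCnvTable, gain_cut: float, loss_cut: float
) -> ProbeCnvTable:
    """Discretize log2-ratio probes: > gain_cut → gain, < loss_cut → loss.

    This is the bridge for cohorts whose array software exports numeric
    ratios instead of discrete calls; values in [loss_cut, gain_cut] are
    normal.
    """
    if not (loss_cut < 0 < gain_cut):
        raise CnvStatusError(
            f"cuts must satisfy loss_cut < 0 < gain_cut, got {loss_cut}, {gain_cut}"
        )
    if table.log_ratios is None:
        raise CnvStatusError("table already holds discrete states")
    lr = table.log_ratios.to_numpy()
    states = np.zeros(lr.shape, dtype=np.int8)
    states[lr > gain_cut] = 1
    states[lr < loss_cut] = -1
    return ProbeCnvTable(
        probes=table.probes,
        states=pd.DataFrame(
            states, index=table.log_ratios.index, columns=table.log_ratios.columns
        ),
        control_samples=table.control_samples,
    )


@dataclass
class FilterCounts:
    constitutional: int
    sex_chromosome: int
    intergenic: int
    altered_in_controls: int

    def as_dict(self) -> dict[str, int]:
        return {
            "constitutional": self.constitutional,
            "sex_chromosome": self.sex_chromosome,
            "intergenic": self.intergenic,
            "altered_in_controls": self.altered_in_controls,
        }


def _region_trees(regions: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if regions is None or len(regions) == 0:
        return trees
    for chrom, sub in regions.groupby(regions["chrom"].map(normalize_chrom)):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"])
        )
    return trees


def filter_probes(
    table: ProbeCnvTable,
    constitutional_regions: pd.DataFrame | None = None,
    sex_chroms: tuple[str, ...] = DEFAULT_SEX_CHROMS,
    control_samples: tuple[str, ...] | None = None,
) -> tuple[ProbeCnvTable, FilterCounts]:
    """Apply the four probe-exclusion rules; returns survivors and counts.

    Constitutional-region overlap uses the any-overlap (≥ 1 bp) rule on
    0-based half-open coordinates.  "Altered in controls" means a non-normal
    state in at least one control sample, the strictest reading.  Removal
    counts are attributed sequentially in the order above, but the surviving
    set is independent of rule order.
    """
    if not table.is_discrete:
        raise CnvStatusError(
            "probe states must be discretized before filtering "
            "(run threshold_logratio_probes first)"
        )
    controls = tuple(
        control_samples if control_samples is not None else table.control_samples
    )
    probes = table.probes
    alive = pd.Series(True, index=probes.index)

    trees = _region_trees(constitutional_regions)
    in_const = np.zeros(len(probes), dtype=bool)
    if trees:
        chroms = probes["chrom"].map(normalize_chrom).to_numpy()
        starts = probes["start"].to_numpy()
        ends = probes["end"].to_numpy()
        for i, (c, s, e) in enumerate(zip(chroms, starts, ends)):
            tree = trees.get(c)
            if tree is not None and tree.overlaps(s, e):
                in_const[i] = True
    n_const = int((alive & in_const).sum())
    alive &= ~in_const

    sex = {normalize_chrom(c) for c in sex_chroms}
    on_sex = probes["chrom"].map(normalize_chrom).isin(sex).to_numpy()
    n_sex = int((alive & on_sex).sum())
    alive &= ~on_sex

    intergenic = np.array([len(g) == 0 for g in probes["gene_ids"]])
    n_inter = int((alive & intergenic).sum())
    alive &= ~intergenic

    if controls:
        ctrl_altered = (table.states[list(controls)] != 0).any(axis=1).to_numpy()
    else:
        ctrl_altered = np.zeros(len(probes), dtype=bool)
    n_ctrl = int((alive & ctrl_altered).sum())
    alive &= ~ctrl_altered

    if not alive.any():
        raise CnvStatusError("no probe survives the exclusion rules")
    counts = FilterCounts(n_const, n_sex, n_inter, n_ctrl)
    return table.subset_probes(probes.index[alive]), counts


@dataclass
class GeneStatusMatrix:
    """Per-gene, per-sample copy-number status (−1 lost, 0 normal, +1 gained)."""

    status: pd.DataFrame
    n_probes: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.status.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.columns)

    def to_labels(self) -> pd.DataFrame:
        from .io import GENE_STATUS_LABELS

        return self.status.replace(GENE_STATUS_LABELS)


def aggregate_gene_status(
    table: ProbeCnvTable, tie_rule: str = "normal"
) -> GeneStatusMatrix:
    """Vote one status per gene per sample from that gene's probe states.

    A multi-gene probe counts toward each of its genes.  ``tie_rule``:

    - ``"normal"`` (default): the state held by a strict plurality of probes
      wins; any tie for the maximum count — including lost-vs-gained and
      non-normal-vs-normal ties — resolves to normal.
    - ``"consensus"``: non-normal only when all probes agree on that state.
    """
    if not table.is_discrete:
        raise CnvStatusError("probe states required for aggregation")
    if tie_rule not in {"normal", "consensus"}:
        raise CnvStatusError(f"unknown tie rule: {tie_rule}")

    # explode probe→gene links
    gene_lists = table.probes["gene_ids"]
    probe_pos: list[int] = []
    gene_names: list[str] = []
    for i, genes in enumerate(gene_lists):
        for g in genes:
            probe_pos.append(i)
            gene_names.append(g)
    if not gene_names:
        raise CnvStatusError("no probe is annotated to a gene")
    genes_index = pd.Index(sorted(set(gene_names)), name="gene_id")
    gene_idx = genes_index.get_indexer(gene_names)
    probe_pos_arr = np.asarray(probe_pos)

    states = table.states.to_numpy()  # probes × samples
    n_genes, n_samples = len(genes_index), states.shape[1]
    counts = np.zeros((3, n_genes, n_samples), dtype=np.int32)  # loss, normal, gain
    for k, code in enumerate((-1, 0, 1)):
        onehot = (states[probe_pos_arr] == code).astype(np.int32)
        np.add.at(counts[k], gene_idx, onehot)

    loss, norm, gain = counts
    if tie_rule == "normal":
        best = np.maximum(np.maximum(loss, norm), gain)
        status = np.zeros((n_genes, n_samples), dtype=np.int8)
        status[(loss == best) & (norm < best) & (gain < best)] = -1
        status[(gain == best) & (norm < best) & (loss < best)] = 1
    else:  # consensus
        total = loss + norm + gain
        status = np.zeros((n_genes, n_samples), dtype=np.int8)
        status[loss == total] = -1
        status[gain == total] = 1

    n_probes = pd.Series(
        np.bincount(gene_idx, minlength=n_genes), index=genes_index, name="n_probes"
    )
    return GeneStatusMatrix(
        status=pd.DataFrame(
            status, index=genes_index, columns=table.states.columns
        ),
        n_probes=n_probes,
    )
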