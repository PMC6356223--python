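"""Expression integration: representative probes, control quartiles, and
concordant CNV+expression alteration calls.

Per gene, the expression probe with the maximum interquartile range (IQRmax)
across samples represents the gene.  A gene is *altered* in a sample when its
copy-number status is lost and its expression falls strictly under the first
quartile of the control group — the samples in which that gene is
copy-normal — or gained with expression strictly above the third quartile.
Control quartiles are only defined when at least ``min_controls`` copy-normal
samples exist (30 by default); otherwise the gene is not evaluable.

Quantiles use linear interpolation at position p·(n−1) of the sorted values
(numpy's default), a convention that matters at small n and is therefore
fixed and recorded in the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import GeneStatusMatrix
from .io import (
    ALTERED_GAIN,
    ALTERED_LOSS,
    NOT_ALTERED,
    NOT_EVALUABLE,
    ExpressionTable,
)


class ExpressionIntegrationError(ValueError):
    pass


@dataclass
class RepresentativeExpression:
    """One chosen probe per gene with its sample values and IQR."""

    gene_id: str
    probe_id: str
    values: pd.Series
    iqr: float


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def select_representative_probes(expr: ExpressionTable) -> pd.DataFrame:
    """IQRmax probe selection for every gene; returns a gene × sample frame.

    Ties in IQR break to the lexicographically smallest probe id.  The chosen
    probe id is attached as the frame's ``probe_id`` column-level metadata via
    the ``attrs`` dict (``frame.attrs["probe_by_gene"]``).
    """
    values = expr.values
    iqr = values.quantile(0.75, axis=1) - values.quantile(0.25, axis=1)
    choice = (
        pd.DataFrame({"gene_id": expr.gene_ids, "iqr": iqr})
        .sort_index()  # probe_id order → first max is lexicographically smallest
        .groupby("gene_id", sort=True)["iqr"]
        .idxmax()
    )
    rep = values.loc[choice.to_numpy()]
    rep.index = pd.Index(choice.index, name="gene_id")
    rep.attrs["probe_by_gene"] = dict(zip(choice.index, choice.to_numpy()))
    return rep


def select_representative_probe(
    expr: ExpressionTable, gene_id: str
) -> RepresentativeExpression:
    """Single-gene IQRmax selection (convenience wrapper)."""
    probes = expr.gene_ids.index[expr.gene_ids == gene_id]
    if len(probes) == 0:
        raise ExpressionIntegrationError(f"gene absent from expression table: {gene_id}")
    iqrs = {p: _iqr(expr.values.loc[p].to_numpy()) for p in probes}
    # tie → lexicographically smallest probe id
    best_iqr = max(iqrs.values())
    probe = min(p for p, v in iqrs.items() if v == best_iqr)
    return RepresentativeExpression(
        gene_id=gene_id,
        probe_id=probe,
        values=expr.values.loc[probe],
        iqr=best_iqr,
    )


def compute_control_stats(
    rep_expr: pd.DataFrame,
    status: GeneStatusMatrix,
    min_controls: int = 30,
) -> pd.DataFrame:
    """Per-gene Q1/Q3 of expression over that gene's copy-normal samples.

    Returns a frame indexed by the status matrix's genes with columns
    ``n_controls``, ``q1``, ``q3``; q1/q3 are NaN where fewer than
    ``min_controls`` copy-normal samples have expression, marking the gene
    not evaluable downstream.  Only a gene's own copy-normal samples enter
    its quartiles (no leakage from altered samples).
    """
    genes = status.status.index
    samples = [s for s in status.status.columns if s in rep_expr.columns]
    stat = status.status[samples].to_numpy()
    expr = rep_expr.reindex(index=genes, columns=samples).to_numpy(dtype=float)

    masked = np.where(stat == 0, expr, np.nan)
    n_ctrl = np.sum(~np.isnan(masked), axis=1)
    q1 = np.full(len(genes), np.nan)
    q3 = np.full(len(genes), np.nan)
    ok = n_ctrl >= min_controls
    if ok.any():
        with np.errstate(all="ignore"):
            q = np.nanpercentile(masked[ok], [25, 75], axis=1)
        q1[ok], q3[ok] = q[0], q[1]
    return pd.DataFrame(
        {"n_controls": n_ctrl.astype(int), "q1": q1, "q3": q3}, index=genes
    )


@dataclass
class AlterationMatrix:
    """Joint CNV+expression call per gene and sample.

    Codes: −1 altered_loss, 0 not_altered, +1 altered_gain, 2 not_evaluable.
    """

    codes: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def evaluable_genes(self) -> pd.Index:
        return self.codes.index[(self.codes != NOT_EVALUABLE).all(axis=1)]

    def is_altered(self) -> pd.DataFrame:
        return self.codes.isin([ALTERED_LOSS, ALTERED_GAIN])

    def to_labels(self) -> pd.DataFrame:
        from .io import ALTERATION_LABELS

        return self.codes.replace(ALTERATION_LABELS)


def call_alterations(
    status: GeneStatusMatrix,
    rep_expr: pd.DataFrame,
    control_stats: pd.DataFrame,
    boundary: str = "strict",
) -> AlterationMatrix:
    """Concordant alteration calling against control-group quartiles.

    altered_loss iff status lost and expression under the control Q1;
    altered_gain iff status gained and expression above the control Q3
    (strict comparisons by default; ``boundary="inclusive"`` admits equality).
    Genes without defined control stats or without expression are
    not_evaluable, as are individual cells with missing expression.
    """
    if boundary not in {"strict", "inclusive"}:
        raise ExpressionIntegrationError(f"unknown boundary rule: {boundary}")
    genes = status.status.index
    samples = list(status.status.columns)
    stat = status.status.to_numpy()
    expr = rep_expr.reindex(index=genes, columns=samples).to_numpy(dtype=float)
    q1 = control_stats.reindex(genes)["q1"].to_numpy()[:, None]
    q3 = control_stats.reindex(genes)["q3"].to_numpy()[:, None]

    if boundary == "strict":
        low = expr < q1
        high = expr > q3
    else:
        low = expr <= q1
        high = expr >= q3

    codes = np.zeros(stat.shape, dtype=np.int8)
    codes[(stat == -1) & low] = ALTERED_LOSS
    codes[(stat == 1) & high] = ALTERED_GAIN
    codes[np.isnan(expr)] = NOT_EVALUABLE
    codes[np.broadcast_to(np.isnan(q1), stat.shape)] = NOT_EVALUABLE
    return AlterationMatrix(
        codes=pd.DataFrame(codes, index=genes, columns=samples)
    )


def alteration_load(alt: AlterationMatrix) -> dict[str, object]:
    """Per-sample altered-gene counts and the cohort gain/loss split.

    Fractions are NaN when no cell is altered.
    """
    altered = alt.is_altered()
    per_sample = altered.sum(axis=0).rename("n_altered")
    n_gain = int((alt.codes == ALTERED_GAIN).to_numpy().sum())
    n_loss = int((alt.codes == ALTERED_LOSS).to_numpy().sum())
    total = n_gain + n_loss
    return {
        "per_sample": per_sample,
        "mean_load": float(per_sample.mean()) if len(per_sample) else float("nan"),
        "gain_fraction": n_gain / total if total else float("nan"),
        "loss_fraction": n_loss / total if total else float("nan"),
        "n_evaluable_genes": int(len(alt.evaluable_genes)),
    }
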