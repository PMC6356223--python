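"""Subgroup-enrichment testing and candidate-driver selection.

Gene (and pathway) alterations are tested for association with a sample
subgroup — typically metastatic versus non-metastatic tumors — with a
two-sided Fisher's exact test on the 2×2 table

    [[altered & subgroup,      altered & rest],
     [not altered & subgroup,  not altered & rest]]

A gene is a candidate driver when its own alteration is enriched in the
subgroup (p < alpha, enriched direction) and at least one pathway it belongs
to satisfies the pathway condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import AlterationMatrix
from .io import NOT_EVALUABLE, PathwayCatalog
from .pathways import PathwayAlterationMatrix

# relative guard admitting tables whose probability ties the observed one up
# to floating-point error (the convention of the reference statistical
# environments)
_TIE_EPS = 1e-7


class EnrichmentError(ValueError):
    pass


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for [[a, b], [c, d]].

    The p-value sums, over the hypergeometric support at fixed margins, the
    probabilities of all tables no more likely than the observed one.
    Returns ``(p, odds_ratio)`` with the sample odds ratio a·d / b·c
    (``inf`` when b·c = 0 < a·d, ``nan`` for 0/0).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise EnrichmentError(f"counts must be non-negative integers, got {v}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise EnrichmentError("all-zero 2x2 table")
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _TIE_EPS)].sum())
    p = min(p, 1.0)

    if b * c == 0:
        oddsr = float("nan") if a * d == 0 else float("inf")
    else:
        oddsr = (a * d) / (b * c)
    return p, oddsr


def chi2_association(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared association test (df = 1) on [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise EnrichmentError("chi-squared test requires positive margins")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def _tables_for_units(
    altered: pd.DataFrame,
    evaluable: pd.DataFrame,
    subgroup: pd.Series,
) -> pd.DataFrame:
    """2×2 counts per row of a boolean unit × sample alteration frame."""
    sub = subgroup.reindex(altered.columns).astype(bool).to_numpy()
    alt = altered.to_numpy(dtype=bool)
    ev = evaluable.to_numpy(dtype=bool)
    a = (alt & ev & sub).sum(axis=1)
    b = (alt & ev & ~sub).sum(axis=1)
    c = (~alt & ev & sub).sum(axis=1)
    d = (~alt & ev & ~sub).sum(axis=1)
    return pd.DataFrame({"a": a, "b": b, "c": c, "d": d}, index=altered.index)


def _enrich(tables: pd.DataFrame, with_chi2: bool, yates: bool) -> pd.DataFrame:
    rows = []
    for unit, (a, b, c, d) in tables.iterrows():
        p, oddsr = fisher_exact_2x2(a, b, c, d)
        freq_sub = a / (a + c) if a + c else np.nan
        freq_rest = b / (b + d) if b + d else np.nan
        if np.isnan(freq_sub) or np.isnan(freq_rest) or freq_sub == freq_rest:
            direction = "neutral"
        elif freq_sub > freq_rest:
            direction = "enriched_in_subgroup"
        else:
            direction = "depleted_in_subgroup"
        row = {
            "a": a, "b": b, "c": c, "d": d,
            "freq_subgroup": freq_sub, "freq_rest": freq_rest,
            "direction": direction, "odds_ratio": oddsr, "p_fisher": p,
        }
        if with_chi2:
            try:
                stat, p_chi2 = chi2_association(a, b, c, d, yates=yates)
            except EnrichmentError:
                stat, p_chi2 = np.nan, np.nan
            row["chi2_statistic"], row["p_chi2"] = stat, p_chi2
        rows.append(row)
    out = pd.DataFrame(rows, index=tables.index)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_fisher"], method="fdr_bh")[1]
        out = out.sort_index().sort_values("p_fisher", kind="mergesort")
    else:
        out["p_adjusted"] = []
    return out


def gene_subgroup_enrichment(
    alt: AlterationMatrix,
    subgroup: pd.Series,
    candidate_pool: frozenset | set | None = None,
    with_chi2: bool = False,
    yates: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of each pool gene's alteration in the subgroup.

    ``subgroup`` is a boolean series over samples (True = subgroup of
    interest).  Samples whose call for a gene is not evaluable are excluded
    from that gene's table.  Results carry Benjamini–Hochberg adjusted
    p-values across the pool and are sorted by raw p.
    """
    sub = subgroup.reindex(alt.sample_ids)
    if sub.isna().any():
        raise EnrichmentError("subgroup labels missing for some samples")
    if not sub.any() or sub.all():
        raise EnrichmentError("subgroup must be a proper, non-empty sample subset")
    genes = alt.codes.index
    if candidate_pool is not None:
        genes = genes.intersection(list(candidate_pool))
    codes = alt.codes.loc[genes]
    altered = codes.isin([-1, 1])
    evaluable = codes != NOT_EVALUABLE
    tables = _tables_for_units(altered, evaluable, sub)
    tables.index.name = "gene_id"
    out = _enrich(tables, with_chi2, yates)
    n_loss = (codes == -1).sum(axis=1)
    n_gain = (codes == 1).sum(axis=1)
    alteration_type = pd.Series(
        np.where(n_loss + n_gain == 0, "none",
                 np.where(n_gain > n_loss, "gain", "loss")),
        index=codes.index,
    )
    out["alteration_type"] = alteration_type.reindex(out.index)
    return out


def pathway_subgroup_enrichment(
    pam: PathwayAlterationMatrix,
    subgroup: pd.Series,
    with_chi2: bool = False,
    yates: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of each pathway's alteration flag in the subgroup."""
    sub = subgroup.reindex(pam.flags.columns)
    if sub.isna().any():
        raise EnrichmentError("subgroup labels missing for some samples")
    flags = pam.flags
    tables = _tables_for_units(flags, pd.DataFrame(True, index=flags.index,
                                                   columns=flags.columns), sub)
    tables.index.name = "pathway_id"
    return _enrich(tables, with_chi2, yates)


def select_candidate_drivers(
    gene_results: pd.DataFrame,
    pathway_results: pd.DataFrame,
    catalog: PathwayCatalog,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    always_pass_pathways: frozenset | set = frozenset(),
) -> pd.DataFrame:
    """Genes enriched in the subgroup whose pathway condition also holds.

    A pathway satisfies the condition when its own enrichment passes
    (p < alpha, enriched direction) or when it belongs to
    ``always_pass_pathways`` — the pipeline passes the universally altered
    pathways there, since a pathway altered in every tumor is maximally
    altered in the subgroup yet yields a degenerate 2×2.
    """
    pcol = "p_adjusted" if use_adjusted else "p_fisher"
    passing_pathways = set(
        pathway_results.index[
            (pathway_results[pcol] < alpha)
            & (pathway_results["direction"] == "enriched_in_subgroup")
        ]
    ) | set(always_pass_pathways)

    gene_to_pathways: dict[str, list[str]] = {}
    for p, genes in catalog.gene_sets.items():
        if p in passing_pathways:
            for g in genes:
                gene_to_pathways.setdefault(g, []).append(p)

    passing_genes = gene_results[
        (gene_results[pcol] < alpha)
        & (gene_results["direction"] == "enriched_in_subgroup")
    ]
    rows = []
    for g, res in passing_genes.iterrows():
        support = sorted(gene_to_pathways.get(g, []))
        if not support:
            continue
        rows.append(
            {
                "gene_id": g,
                "alteration_type": res.get("alteration_type", "unknown"),
                "p_fisher": res["p_fisher"],
                "p_adjusted": res["p_adjusted"],
                "odds_ratio": res["odds_ratio"],
                "supporting_pathways": ",".join(support),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "alteration_type", "p_fisher", "p_adjusted",
            "odds_ratio", "supporting_pathways",
        ],
    )
    return out.set_index("gene_id")
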