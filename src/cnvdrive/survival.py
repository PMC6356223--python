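"""Expression dichotomization and metastasis-free-survival comparison.

The expression cutoff separating "low" from "high" tumors is found where the
kernel-density curves of the copy-lost and copy-normal groups intersect
(with a mean cutoff or a fixed value as alternatives).  Strata are then
compared on metastasis-free survival (MFS) with the Kaplan-Meier estimator,
the two-group log-rank test, and the O/E hazard ratio
(O₁/E₁)/(O₂/E₂) whose confidence interval uses the standard
log-scale variance 1/E₁ + 1/E₂.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cnv import GeneStatusMatrix
from .io import CohortBundle


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dichotomization


@dataclass
class ThresholdResult:
    gene_id: str
    method: str  # density_intersection | mean | fixed
    threshold: float
    group_sizes: tuple[int, int]
    fallback: bool = False
    density_grid: pd.DataFrame | None = None


def density_intersection_threshold(
    values_a: np.ndarray,
    values_b: np.ndarray,
    bandwidth_rule: str = "silverman",
    grid_size: int = 1024,
    gene_id: str = "",
) -> ThresholdResult:
    """Expression cutoff at the crossing of two Gaussian kernel densities.

    Group A is the copy-lost (low) group, B the copy-normal group.  Densities
    are evaluated on a shared grid spanning the pooled range extended by three
    pooled bandwidths; candidate cutoffs are the sign changes of f_A − f_B,
    restricted to the interval between the two group medians (overlapping
    unimodal densities also cross in the tails; the biologically meaningful
    separator lies between the modes).  With several candidates the one
    nearest the midpoint of the medians wins; crossings are refined by linear
    interpolation between grid points.  Degenerate inputs fall back to the
    midpoint of group means; a missing central crossing falls back to the
    pooled mean, both with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SurvivalError("each group needs at least two values")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance group; falling back to midpoint of means")
        thr = float((a.mean() + b.mean()) / 2)
        return ThresholdResult(gene_id, "density_intersection", thr,
                               (len(a), len(b)), fallback=True)

    kde_a = stats.gaussian_kde(a, bw_method=bandwidth_rule)
    kde_b = stats.gaussian_kde(b, bw_method=bandwidth_rule)
    bw = max(kde_a.factor * a.std(ddof=1), kde_b.factor * b.std(ddof=1))
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min() - 3 * bw, pooled.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    fa = kde_a(grid)
    fb = kde_b(grid)
    diff = fa - fb

    med_a, med_b = np.median(a), np.median(b)
    w_lo, w_hi = min(med_a, med_b), max(med_a, med_b)
    sign = np.sign(diff)
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    crossings = []
    for i in change:
        # linear interpolation of the zero of diff between grid[i], grid[i+1]
        x0, x1, y0, y1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        x = x0 - y0 * (x1 - x0) / (y1 - y0)
        if w_lo <= x <= w_hi:
            crossings.append(x)

    density_grid = pd.DataFrame({"x": grid, "f_lost": fa, "f_normal": fb})
    if crossings:
        mid = (med_a + med_b) / 2
        thr = float(min(crossings, key=lambda x: abs(x - mid)))
        fallback = False
    else:
        warnings.warn(
            "no density crossing between group medians; using pooled mean"
        )
        thr = float(pooled.mean())
        fallback = True
    return ThresholdResult(
        gene_id, "density_intersection", thr, (len(a), len(b)),
        fallback=fallback, density_grid=density_grid,
    )


def dichotomize(
    values: pd.Series, method: str, threshold: float | None = None
) -> tuple[pd.Series, float]:
    """Label samples low/high around a cutoff: low iff value < cutoff.

    ``method`` is one of ``mean`` (cutoff = mean of values), ``fixed`` or
    ``density_intersection`` (cutoff passed in ``threshold``).
    Returns the label series ('low'/'high') and the cutoff used.
    """
    if method == "mean":
        cut = float(values.mean())
    elif method in {"fixed", "density_intersection"}:
        if threshold is None:
            raise SurvivalError(f"method {method!r} requires an explicit threshold")
        cut = float(threshold)
    else:
        raise SurvivalError(f"unknown dichotomization method: {method}")
    labels = pd.Series(
        np.where(values < cut, "low", "high"), index=values.index, name="stratum"
    )
    if labels.nunique() < 2:
        warnings.warn("all samples fall on one side of the cutoff")
    return labels, cut


# ---------------------------------------------------------------------------
# survival estimation and comparison


@dataclass
class SurvivalCurve:
    """Product-limit estimate: event times with at-risk/event counts."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    label: str = ""


def km_estimate(times, events, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier estimator with right censoring.

    At tied times, deaths are counted before censorings (the standard
    convention of the product-limit estimator).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise SurvivalError("empty survival input")
    if (times < 0).any():
        raise SurvivalError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "km")
    table = kmf.event_table
    return SurvivalCurve(
        times=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
        survival=kmf.survival_function_.iloc[:, 0].reindex(table.index).to_numpy(),
        label=label,
    )


@dataclass
class LogRankResult:
    statistic: float
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    hazard_ratio: float
    hr_ci: tuple[float, float]
    group_labels: tuple[str, str] = ("", "")
    n: tuple[int, int] = (0, 0)


def logrank_and_hr(
    times, events, groups, ci_level: float = 0.95, group1: str | None = None
) -> LogRankResult:
    """Two-group log-rank test plus the O/E hazard-ratio estimate.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation given the at-risk sets; the
    statistic (O₁−E₁)²/V is referred to chi-squared with one degree of
    freedom.  The hazard ratio is (O₁/E₁)/(O₂/E₂) — group 1 is the
    lexicographically first label — with a log-scale CI from 1/E₁ + 1/E₂.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = list(np.unique(groups))
    if len(labels) != 2:
        raise SurvivalError(f"log-rank needs exactly two groups, got {labels}")
    if group1 is not None:
        if group1 not in labels:
            raise SurvivalError(f"group1={group1!r} not among labels {labels}")
        labels.sort(key=lambda x: x != group1)  # put group1 first
    g1 = groups == labels[0]

    o1 = e1 = v = 0.0
    event_times = np.unique(times[events == 1])
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    total_events = float(events.sum())
    o2 = total_events - o1
    e2 = total_events - e1
    if v > 0:
        statistic = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(statistic, df=1))
    else:
        statistic, p = 0.0, 1.0

    if e1 > 0 and e2 > 0 and o1 > 0 and o2 > 0:
        hr = (o1 / e1) / (o2 / e2)
        z = stats.norm.ppf(0.5 + ci_level / 2)
        se = np.sqrt(1 / e1 + 1 / e2)
        ci = (float(hr * np.exp(-z * se)), float(hr * np.exp(z * se)))
    elif o1 == 0 or o2 == 0:
        hr = 0.0 if o1 == 0 and o2 > 0 else float("inf") if o2 == 0 and o1 > 0 else float("nan")
        ci = (float("nan"), float("nan"))
    else:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    return LogRankResult(
        statistic=float(statistic), p=p,
        observed=(float(o1), float(o2)), expected=(float(e1), float(e2)),
        hazard_ratio=float(hr), hr_ci=ci,
        group_labels=(str(labels[0]), str(labels[1])),
        n=(int(g1.sum()), int((~g1).sum())),
    )


# ---------------------------------------------------------------------------
# cohort-level MFS analysis


@dataclass
class MfsAnalysis:
    gene_id: str
    threshold: ThresholdResult
    strata: pd.Series
    curves: dict[str, SurvivalCurve]
    logrank: LogRankResult
    n_excluded_metastatic_at_diagnosis: int = 0


def mfs_analysis(
    bundle: CohortBundle,
    gene_id: str,
    rep_expr: pd.DataFrame,
    status: GeneStatusMatrix,
    method: str = "density_intersection",
    threshold: float | None = None,
    subset: str = "all",
    exclude_metastatic_at_diagnosis: bool = True,
    bandwidth_rule: str = "silverman",
    grid_size: int = 1024,
) -> MfsAnalysis:
    """Dichotomize a gene's expression and compare MFS between strata.

    ``subset`` restricts the cohort to ``chemo`` / ``no_chemo`` patients
    (unknown chemotherapy status is excluded from either subset, and a subset
    with only unknown statuses is a hard error).  For the density method the
    two density groups are the copy-lost and copy-normal samples of the gene.
    """
    clin = bundle.clinical.data
    if exclude_metastatic_at_diagnosis:
        n_excl = int(clin["metastatic_at_diagnosis"].sum())
        clin = clin[~clin["metastatic_at_diagnosis"]]
    else:
        n_excl = 0

    if subset in {"chemo", "no_chemo"}:
        chemo = clin["chemotherapy"]
        if chemo.isna().all():
            raise SurvivalError(
                "chemotherapy status unknown for all samples; cannot form "
                f"subset {subset!r} (column 'chemotherapy')"
            )
        clin = clin[chemo == (subset == "chemo")]
    elif subset != "all":
        raise SurvivalError(f"unknown subset: {subset}")
    if clin.empty:
        raise SurvivalError(f"subset {subset!r} contains no sample")

    if gene_id not in rep_expr.index:
        raise SurvivalError(f"gene without representative expression: {gene_id}")
    values = rep_expr.loc[gene_id].reindex(clin.index).dropna()
    clin = clin.loc[values.index]

    if method == "density_intersection" and threshold is None:
        gstat = status.status.loc[gene_id].reindex(values.index)
        lost = values[gstat == -1].to_numpy()
        normal = values[gstat == 0].to_numpy()
        if len(lost) < 2 or len(normal) < 2:
            raise SurvivalError(
                f"gene {gene_id}: too few copy-lost or copy-normal samples "
                "for a density threshold"
            )
        thr_res = density_intersection_threshold(
            lost, normal, bandwidth_rule=bandwidth_rule,
            grid_size=grid_size, gene_id=gene_id,
        )
        threshold = thr_res.threshold
        strata, _ = dichotomize(values, "fixed", threshold)
    else:
        strata, cut = dichotomize(values, method, threshold)
        thr_res = ThresholdResult(
            gene_id, method, cut,
            (int((strata == "low").sum()), int((strata == "high").sum())),
        )

    if strata.nunique() < 2:
        raise SurvivalError("single-stratum cohort; survival comparison skipped")

    curves = {}
    for label in ("low", "high"):
        mask = strata == label
        curves[label] = km_estimate(
            clin.loc[mask, "mfs_time"], clin.loc[mask, "event"], label=label
        )
    lr = logrank_and_hr(
        clin["mfs_time"].to_numpy(), clin["event"].to_numpy(), strata.to_numpy(),
        group1="low",
    )
    thr_res.group_sizes = (int((strata == "low").sum()), int((strata == "high").sum()))
    return MfsAnalysis(
        gene_id=gene_id, threshold=thr_res, strata=strata,
        curves=curves, logrank=lr,
        n_excluded_metastatic_at_diagnosis=n_excl,
    )
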