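"""Shared data model and file I/O for tumor-cohort CNV/expression analyses.

All tables travel as plain tab- or comma-separated text so that fixtures are
diffable and runs are byte-reproducible.  Copy-number states and gene statuses
are held internally as ``int8`` codes (−1 loss/lost, 0 normal, +1 gain/gained)
and converted to the string vocabulary at the file boundary.  Genomic
coordinates are 0-based half-open (BED convention) everywhere in memory; a
1-based input can be declared in the loader and is converted once on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cnvdrive")

# ---------------------------------------------------------------------------
# state vocabularies

PROBE_STATE_CODES = {"loss": -1, "normal": 0, "gain": 1}
PROBE_STATE_LABELS = {v: k for k, v in PROBE_STATE_CODES.items()}

GENE_STATUS_CODES = {"lost": -1, "normal": 0, "gained": 1}
GENE_STATUS_LABELS = {v: k for k, v in GENE_STATUS_CODES.items()}

# joint CNV+expression call
ALTERED_LOSS = -1
NOT_ALTERED = 0
ALTERED_GAIN = 1
NOT_EVALUABLE = 2
ALTERATION_CODES = {
    "altered_loss": ALTERED_LOSS,
    "not_altered": NOT_ALTERED,
    "altered_gain": ALTERED_GAIN,
    "not_evaluable": NOT_EVALUABLE,
}
ALTERATION_LABELS = {v: k for k, v in ALTERATION_CODES.items()}


class CohortIOError(ValueError):
    """Malformed or inconsistent input data."""


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome name without the ``chr`` prefix ('chrX' == 'X')."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ProbeCnvTable:
    """Probe-level copy-number data for tumor and control samples.

    ``probes`` is indexed by probe_id with columns chrom, start, end and
    gene_ids (tuple of gene identifiers, possibly empty).  Exactly one of
    ``states`` (int8 codes) or ``log_ratios`` (float) is set; both are
    probe × sample frames sharing the probe index.
    """

    probes: pd.DataFrame
    states: pd.DataFrame | None = None
    log_ratios: pd.DataFrame | None = None
    control_samples: tuple[str, ...] = ()

    @property
    def is_discrete(self) -> bool:
        return self.states is not None

    @property
    def values(self) -> pd.DataFrame:
        return self.states if self.states is not None else self.log_ratios

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        ctrl = set(self.control_samples)
        return [s for s in self.sample_ids if s not in ctrl]

    def validate(self) -> None:
        if (self.states is None) == (self.log_ratios is None):
            raise CohortIOError(
                "probe table must carry exactly one of states / log-ratios"
            )
        if self.probes.index.has_duplicates:
            dups = self.probes.index[self.probes.index.duplicated()].unique()
            raise CohortIOError(f"duplicate probe ids: {list(dups)[:5]}")
        bad = self.probes["start"] >= self.probes["end"]
        if bad.any():
            raise CohortIOError(
                f"probe coordinates with start >= end: "
                f"{list(self.probes.index[bad])[:5]}"
            )
        if not self.values.index.equals(self.probes.index):
            raise CohortIOError("state/log-ratio rows do not match probe index")
        missing = set(self.control_samples) - set(self.sample_ids)
        if missing:
            raise CohortIOError(f"control samples absent from table: {missing}")

    def subset_probes(self, keep: pd.Index | Iterable[str]) -> "ProbeCnvTable":
        keep = pd.Index(keep)
        return ProbeCnvTable(
            probes=self.probes.loc[keep],
            states=None if self.states is None else self.states.loc[keep],
            log_ratios=None
            if self.log_ratios is None
            else self.log_ratios.loc[keep],
            control_samples=self.control_samples,
        )

    def subset_samples(self, samples: Iterable[str]) -> "ProbeCnvTable":
        cols = [s for s in self.sample_ids if s in set(samples)]
        return ProbeCnvTable(
            probes=self.probes,
            states=None if self.states is None else self.states[cols],
            log_ratios=None if self.log_ratios is None else self.log_ratios[cols],
            control_samples=tuple(s for s in self.control_samples if s in set(samples)),
        )


@dataclass
class ExpressionTable:
    """Probe-level log2 expression with a probe→gene map.

    ``values`` is probe × sample; ``gene_ids`` maps probe_id → gene_id
    (a gene may own several probes).
    """

    values: pd.DataFrame
    gene_ids: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise CohortIOError("duplicate expression probe ids")
        if not self.gene_ids.index.equals(self.values.index):
            raise CohortIOError("probe→gene map does not match expression rows")
        if self.values.isna().all(axis=None):
            raise CohortIOError("expression table is empty")

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionTable":
        cols = [s for s in self.sample_ids if s in set(samples)]
        return ExpressionTable(values=self.values[cols], gene_ids=self.gene_ids)


CLINICAL_COLUMNS = [
    "metastasis",
    "mfs_time",
    "event",
    "chemotherapy",
    "histotype",
    "metastatic_at_diagnosis",
]


@dataclass
class ClinicalTable:
    """Sample-level outcome data (metastasis-free survival and covariates).

    ``chemotherapy`` is a nullable boolean: an unknown treatment status stays
    missing and is never coerced to False.
    """

    data: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortIOError(f"clinical table missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise CohortIOError("duplicate sample ids in clinical table")
        bad = self.data.index[self.data["mfs_time"] < 0]
        if len(bad):
            raise CohortIOError(f"negative mfs_time for samples: {list(bad)[:5]}")
        incoherent = self.data.index[
            (self.data["event"] == 1) & (~self.data["metastasis"].astype(bool))
        ]
        if len(incoherent):
            raise CohortIOError(
                f"event=1 without metastasis for samples: {list(incoherent)[:5]}"
            )

    def subset_samples(self, samples: Iterable[str]) -> "ClinicalTable":
        keep = [s for s in self.data.index if s in set(samples)]
        return ClinicalTable(self.data.loc[keep])


@dataclass
class PathwayCatalog:
    """Flat pathway membership: pathway id → gene-id set, optional names."""

    gene_sets: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.gene_sets)

    def validate(self) -> None:
        empty = [p for p, g in self.gene_sets.items() if not g]
        if empty:
            raise CohortIOError(f"pathways with empty gene sets: {empty[:5]}")


@dataclass
class CohortBundle:
    """The four validated input tables, restricted to a common sample set."""

    cnv: ProbeCnvTable
    expr: ExpressionTable
    clinical: ClinicalTable
    pathways: PathwayCatalog
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.clinical.sample_ids


# ---------------------------------------------------------------------------
# readers


def read_probe_cnv(
    path: str | Path,
    control_samples: Iterable[str] = (),
    controls_path: str | Path | None = None,
    one_based: bool = False,
) -> ProbeCnvTable:
    """Read the probe CNV TSV (probe_id, chrom, start, end, gene_ids, samples…).

    Sample columns hold either state tokens (loss/normal/gain) or numeric log2
    ratios, uniformly.  ``controls_path`` points at a one-id-per-line list of
    control samples.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "start", "end", "gene_ids"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: missing columns {missing}")
    df = df.set_index("probe_id")
    sample_cols = [c for c in df.columns if c not in required[1:]]
    if not sample_cols:
        raise CohortIOError(f"{path}: no sample columns found")

    probes = df[["chrom", "start", "end"]].copy()
    probes["start"] = probes["start"].astype(np.int64)
    probes["end"] = probes["end"].astype(np.int64)
    if one_based:
        probes["start"] -= 1
    probes["gene_ids"] = [
        tuple(g for g in str(v).split(",") if g) if pd.notna(v) else ()
        for v in df["gene_ids"]
    ]

    mat = df[sample_cols]
    if controls_path is not None:
        with open(controls_path) as fh:
            control_samples = tuple(
                line.strip() for line in fh if line.strip()
            )
    controls = tuple(control_samples)

    first = mat.iloc[:, 0] if len(mat) else pd.Series(dtype=object)
    tokens = set(PROBE_STATE_CODES)
    if len(mat) and mat.dtypes.apply(lambda d: d == object).all() and set(
        map(str, first.unique())
    ) <= tokens | {"nan"}:
        bad = ~mat.isin(list(tokens)).all(axis=None)
        codes = mat.apply(lambda col: col.map(PROBE_STATE_CODES))
        if codes.dtypes.apply(lambda d: d == object).any() or bad:
            raise CohortIOError(f"{path}: unknown probe state token")
        table = ProbeCnvTable(
            probes=probes, states=codes.astype(np.int8), control_samples=controls
        )
    else:
        table = ProbeCnvTable(
            probes=probes,
            log_ratios=mat.astype(float),
            control_samples=controls,
        )
    table.validate()
    return table


def read_expression(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise CohortIOError(f"{path}: missing column {col}")
    df = df.set_index("probe_id")
    table = ExpressionTable(
        values=df.drop(columns="gene_id").astype(float),
        gene_ids=df["gene_id"],
    )
    table.validate()
    return table


_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_nullable_bool(series: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return pd.NA
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        if s in {"", "na", "nan", "unknown", "?"}:
            return pd.NA
        raise CohortIOError(f"unparsable boolean value: {v!r}")

    return pd.Series(
        [one(v) for v in series], index=series.index, dtype="boolean"
    )


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise CohortIOError(f"{path}: missing column sample_id")
    df = df.set_index("sample_id")
    if "metastatic_at_diagnosis" not in df.columns:
        df["metastatic_at_diagnosis"] = False
    out = pd.DataFrame(index=df.index)
    out["metastasis"] = _parse_nullable_bool(df["metastasis"]).fillna(False).astype(bool)
    out["mfs_time"] = df["mfs_time"].astype(float)
    out["event"] = df["event"].astype(int)
    out["chemotherapy"] = _parse_nullable_bool(df["chemotherapy"])
    out["histotype"] = df["histotype"].astype(str)
    out["metastatic_at_diagnosis"] = (
        _parse_nullable_bool(df["metastatic_at_diagnosis"]).fillna(False).astype(bool)
    )
    table = ClinicalTable(out)
    table.validate()
    return table


def read_pathways(
    path: str | Path, names_path: str | Path | None = None
) -> PathwayCatalog:
    """Read the two-column membership TSV (pathway_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pathway_id", "gene_id"):
        if col not in df.columns:
            raise CohortIOError(f"{path}: missing column {col}")
    gene_sets = {
        p: frozenset(g)
        for p, g in df.groupby("pathway_id", sort=True)["gene_id"]
    }
    names: dict[str, str] = {}
    if names_path is not None:
        ndf = pd.read_csv(names_path, sep="\t", dtype=str)
        names = dict(zip(ndf.iloc[:, 0], ndf.iloc[:, 1]))
    catalog = PathwayCatalog(gene_sets=gene_sets, names=names)
    catalog.validate()
    return catalog


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    """Read a headerless BED (chrom, start, end[, …]) into a frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def load_cohort(
    cnv_path: str | Path,
    expr_path: str | Path,
    clinical_path: str | Path,
    pathway_path: str | Path,
    controls_path: str | Path | None = None,
    pathway_names_path: str | Path | None = None,
    one_based: bool = False,
) -> CohortBundle:
    """Load and cross-validate the four cohort inputs.

    Tumor samples are restricted to the intersection of the CNV, expression
    and clinical sample sets; samples missing from any table are dropped with
    a warning.  A zero intersection is a hard error.
    """
    cnv = read_probe_cnv(cnv_path, controls_path=controls_path, one_based=one_based)
    expr = read_expression(expr_path)
    clinical = read_clinical(clinical_path)
    pathways = read_pathways(pathway_path, names_path=pathway_names_path)

    sets = {
        "cnv": set(cnv.tumor_samples),
        "expression": set(expr.sample_ids),
        "clinical": set(clinical.sample_ids),
    }
    common = sets["cnv"] & sets["expression"] & sets["clinical"]
    if not common:
        raise CohortIOError(
            "no sample shared by CNV, expression and clinical tables"
        )
    dropped = {
        name: sorted(ids - common) for name, ids in sets.items() if ids - common
    }
    for name, ids in dropped.items():
        logger.warning(
            "dropping %d sample(s) present in %s but not all tables: %s",
            len(ids), name, ids[:10],
        )
    keep = common | set(cnv.control_samples)
    bundle = CohortBundle(
        cnv=cnv.subset_samples(keep),
        expr=expr.subset_samples(common),
        clinical=clinical.subset_samples(common),
        pathways=pathways,
        dropped_samples=dropped,
    )
    logger.info(
        "loaded cohort: %d probes, %d expression probes, %d samples, %d pathways",
        len(cnv.probes), len(expr.values), len(common), len(pathways.gene_sets),
    )
    return bundle


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)


def write_probe_cnv(
    table: ProbeCnvTable, path: str | Path, controls_path: str | Path | None = None
) -> None:
    df = table.probes.copy()
    df["gene_ids"] = [",".join(g) for g in df["gene_ids"]]
    if table.is_discrete:
        mat = table.states.replace(PROBE_STATE_LABELS)
    else:
        mat = table.log_ratios.round(6)
    out = pd.concat([df, mat], axis=1)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    if controls_path is not None:
        Path(controls_path).write_text(
            "".join(f"{s}\n" for s in table.control_samples)
        )


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    out = pd.concat([table.gene_ids.rename("gene_id"), table.values.round(6)], axis=1)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    df = table.data.copy()
    df["chemotherapy"] = [
        "unknown" if pd.isna(v) else str(bool(v)) for v in df["chemotherapy"]
    ]
    df["mfs_time"] = df["mfs_time"].round(6)
    df.index.name = "sample_id"
    df.to_csv(path)


def write_pathways(
    catalog: PathwayCatalog, path: str | Path, names_path: str | Path | None = None
) -> None:
    rows = [
        (p, g)
        for p in sorted(catalog.gene_sets)
        for g in sorted(catalog.gene_sets[p])
    ]
    pd.DataFrame(rows, columns=["pathway_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
    if names_path is not None and catalog.names:
        pd.DataFrame(
            sorted(catalog.names.items()), columns=["pathway_id", "name"]
        ).to_csv(names_path, sep="\t", index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write every tabular result as TSV plus a JSON run manifest.

    ``results`` maps short names to DataFrames/Series (written as
    ``<name>.tsv``) or JSON-serializable objects (collected into the
    manifest).  Returns the paths written.  Reruns with identical inputs are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, object] = {}
    for name, obj in results.items():
        if isinstance(obj, (pd.DataFrame, pd.Series)):
            p = out_dir / f"{name}.tsv"
            frame = obj.to_frame() if isinstance(obj, pd.Series) else obj
            frame.to_csv(p, sep="\t", float_format="%.6g")
            written.append(p)
            manifest.setdefault("tables", {})[name] = file_sha256(p)  # type: ignore[union-attr]
        else:
            manifest[name] = obj
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written.append(mpath)
    return written
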