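"""Pathway-level alteration flags and universal-pathway selection.

A pathway is flagged in a sample when at least one of its member genes
(restricted to the evaluable gene universe) carries a concordant alteration
there; "universal" pathways are flagged in every tumor of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import AlterationMatrix
from .io import PathwayCatalog


def restrict_catalog(
    catalog: PathwayCatalog, alt: AlterationMatrix
) -> tuple[PathwayCatalog, int]:
    """Intersect each pathway's gene set with the evaluable gene universe.

    The universe is the set of genes present in the alteration matrix with a
    defined (evaluable) call.  Pathways left empty are dropped; the count of
    dropped pathways is returned alongside.
    """
    universe = set(alt.evaluable_genes)
    gene_sets = {}
    dropped = 0
    for p, genes in catalog.gene_sets.items():
        kept = genes & universe
        if kept:
            gene_sets[p] = frozenset(kept)
        else:
            dropped += 1
    return PathwayCatalog(gene_sets=gene_sets, names=catalog.names), dropped


@dataclass
class PathwayAlterationMatrix:
    """Pathway × sample boolean flags plus the gene universe used."""

    flags: pd.DataFrame
    gene_universe: frozenset

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.flags.index)

    def samples_altered(self) -> pd.Series:
        return self.flags.sum(axis=1).rename("n_samples_altered")


def flag_pathways(
    catalog: PathwayCatalog, alt: AlterationMatrix
) -> PathwayAlterationMatrix:
    """Flag pathway × sample cells with ≥ 1 altered member gene."""
    altered = alt.is_altered()
    rows = {}
    for p, genes in catalog.gene_sets.items():
        members = altered.index.intersection(list(genes))
        if len(members):
            rows[p] = altered.loc[members].any(axis=0)
        else:
            rows[p] = pd.Series(False, index=altered.columns)
    flags = pd.DataFrame(rows).T.reindex(list(catalog.gene_sets))
    flags.index.name = "pathway_id"
    universe = frozenset(alt.evaluable_genes) & frozenset().union(
        *catalog.gene_sets.values()
    ) if catalog.gene_sets else frozenset()
    return PathwayAlterationMatrix(flags=flags.astype(bool), gene_universe=universe)


def select_universal_pathways(
    pam: PathwayAlterationMatrix, fraction: float = 1.0
) -> list[str]:
    """Pathways flagged in at least ``fraction`` of samples (default: all)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = pam.flags.shape[1]
    frac = pam.flags.sum(axis=1) / n if n else pd.Series(dtype=float)
    sel = pam.flags.index[frac >= fraction]
    return list(sel)


def genes_in_universal_pathways(
    selected: list[str], catalog: PathwayCatalog, alt: AlterationMatrix
) -> frozenset:
    """Candidate gene pool: members of selected pathways altered in ≥ 1 sample."""
    members = frozenset().union(
        *(catalog.gene_sets[p] for p in selected)
    ) if selected else frozenset()
    altered_any = alt.is_altered().any(axis=1)
    ever_altered = set(altered_any.index[altered_any])
    return frozenset(members & ever_altered)
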