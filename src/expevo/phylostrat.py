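"""Phylostratigraphic gene-age assignment from an ortholog presence/absence
matrix over an ordered taxon hierarchy.

A gene's phylostratum is the *oldest* taxonomic level at which a homolog is
detectable: strata are scanned oldest to youngest and the first stratum
containing at least one taxon with a hit wins, regardless of absences at
intermediate levels (losses do not rejuvenate a gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

UNCLASSIFIED = "others"


@dataclass(frozen=True)
class StratumHierarchy:
    """Ordered strata (oldest first), each a named set of reference taxa."""

    strata: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self):
        if not self.strata:
            raise ValueError("hierarchy must contain at least one stratum")
        names = [s for s, _ in self.strata]
        if len(set(names)) != len(names):
            raise ValueError("duplicate stratum names")
        for name, taxa in self.strata:
            if not taxa:
                raise ValueError(f"stratum {name!r} has no taxa")

    @property
    def names(self) -> list[str]:
        return [s for s, _ in self.strata]


@dataclass(frozen=True)
class PhylostratumAssignment:
    gene_id: str
    stratum: str
    is_functional: bool


def assign_stratum(
    presence: dict[str, bool], hierarchy: StratumHierarchy, focal_taxon: str
) -> str:
    """Oldest stratum with a detectable homolog for one gene.

    ``presence`` maps taxon -> homolog detected. The focal taxon must be in
    the map (the gene exists there by construction). A gene with no hits in
    any stratum's taxa falls into the "others" bucket — this only happens
    when the hierarchy lacks an orphan stratum listing the focal taxon.
    """
    if focal_taxon not in presence:
        raise KeyError(f"focal taxon {focal_taxon!r} absent from presence map")
    for name, taxa in hierarchy.strata:
        if any(presence.get(t, False) for t in taxa):
            return name
    return UNCLASSIFIED


def assign_all(
    presence_matrix: pd.DataFrame,
    hierarchy: StratumHierarchy,
    focal_taxon: str,
    flags: dict[str, bool],
) -> list[PhylostratumAssignment]:
    """Assign every gene in a presence/absence matrix (rows genes, cols taxa)."""
    out = []
    for gene in presence_matrix.index:
        row = presence_matrix.loc[gene]
        stratum = assign_stratum(row.to_dict(), hierarchy, focal_taxon)
        if gene not in flags:
            raise KeyError(f"no annotation flag for gene {gene!r}")
        out.append(PhylostratumAssignment(gene, stratum, bool(flags[gene])))
    return out


def stratum_table(
    assignments: list[PhylostratumAssignment], hierarchy: StratumHierarchy
) -> pd.DataFrame:
    """Counts of hypothetical/functional genes per stratum, oldest first.

    Rows partition the gene set; a trailing "others" row appears only when
    some gene could not be classified.
    """
    order = hierarchy.names
    if any(a.stratum == UNCLASSIFIED for a in assignments):
        order = order + [UNCLASSIFIED]
    counts = {s: [0, 0] for s in order}
    for a in assignments:
        counts[a.stratum][1 if a.is_functional else 0] += 1
    return pd.DataFrame(
        {
            "stratum": order,
            "hypothetical": [counts[s][0] for s in order],
            "functional": [counts[s][1] for s in order],
        }
    ).set_index("stratum")
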