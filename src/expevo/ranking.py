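"""Fold-change differentials (FCD) and the ranked gene priority list.

For each single-copy ortholog cluster, the extant species' stage-to-stage
fold changes X are contrasted with the reconstructed fold changes Y of an
ancestral node (the five-species MRCA by default):

    FCD = max over transitions t of (X_t - Y_t)

where X_t and Y_t are the log2 fold changes across transition t. Genes are
ranked by this maximum, largest evolved increase first — the prioritization
used to pick knockout candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestral import bm_reconstruct, node_lookup
from .io import ScogMap, transition_label
from .tree import PhyloTree


@dataclass(frozen=True)
class FcdRecord:
    """Per-cluster fold-change differential against an ancestral node."""

    cluster_id: str
    gene_id: str  # member gene in the focal species
    fcd_per_transition: np.ndarray  # log2 scale (or linear differences)
    fcd_max: float
    argmax_t: int
    transition_label: str
    fcd_linear: float  # 2**fcd_max on the log2 scale
    rank: int | None = None

    def with_rank(self, rank: int) -> "FcdRecord":
        return FcdRecord(
            self.cluster_id,
            self.gene_id,
            self.fcd_per_transition,
            self.fcd_max,
            self.argmax_t,
            self.transition_label,
            self.fcd_linear,
            rank,
        )


def fcd(
    extant_delta,
    ancestral_delta,
    cluster_id: str = "",
    gene_id: str = "",
    scale: str = "log2",
) -> FcdRecord:
    """FCD of one cluster: per-transition differential, max, argmax.

    ``scale="log2"`` (default) differences the log2 fold changes directly;
    ``scale="linear_difference"`` differences the linear fold-change ratios
    (2**X_t - 2**Y_t). Ties on the max take the first transition.
    """
    x = np.asarray(extant_delta, dtype=float)
    y = np.asarray(ancestral_delta, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: extant {x.shape} vs ancestral {y.shape}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite fold change")
    if scale == "log2":
        per_t = x - y
    elif scale == "linear_difference":
        per_t = np.exp2(x) - np.exp2(y)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    t = int(np.argmax(per_t))
    fmax = float(per_t[t])
    linear = float(2.0**fmax) if scale == "log2" else fmax
    return FcdRecord(
        cluster_id=cluster_id,
        gene_id=gene_id,
        fcd_per_transition=per_t,
        fcd_max=fmax,
        argmax_t=t,
        transition_label=transition_label(t),
        fcd_linear=linear,
    )


def rank_clusters(records: list[FcdRecord]) -> list[FcdRecord]:
    """Sort by FCD descending (ties: cluster id ascending); assign ranks 1..N."""
    seen: set[str] = set()
    for r in records:
        if r.cluster_id in seen:
            raise ValueError(f"duplicate cluster {r.cluster_id!r}")
        seen.add(r.cluster_id)
    ordered = sorted(records, key=lambda r: (-r.fcd_max, r.cluster_id))
    return [r.with_rank(i + 1) for i, r in enumerate(ordered)]


def top_k(records: list[FcdRecord], k: int) -> list[FcdRecord]:
    """The k best-ranked records (records must already carry ranks)."""
    if any(r.rank is None for r in records):
        raise ValueError("records are unranked; call rank_clusters first")
    return sorted(records, key=lambda r: r.rank)[:k]


def contrast_against_node(
    fold_changes_by_species: dict[str, pd.DataFrame],
    tree: PhyloTree,
    scog_map: ScogMap,
    focal_species: str,
    node_name: str | None = None,
    scale: str = "log2",
) -> list[FcdRecord]:
    """Ranked FCD records for one focal species against one ancestral node.

    ``fold_changes_by_species`` maps species -> DataFrame of log2 fold
    changes indexed by *cluster id* (columns: transitions). Each character
    (cluster x transition) is reconstructed independently under Brownian
    motion, Y is read off at ``node_name`` (default: the root/MRCA), and
    FCD = X - Y is ranked for the focal species.
    """
    if focal_species not in tree.leaf_names:
        raise ValueError(f"focal species {focal_species!r} is not a leaf of the tree")
    missing = [sp for sp in tree.leaf_names if sp not in fold_changes_by_species]
    if missing:
        raise ValueError(f"fold changes missing for species: {missing}")
    if node_name is None:
        node_name = tree.root_name

    clusters = list(scog_map.cluster_ids)
    ref = fold_changes_by_species[focal_species]
    transitions = list(ref.columns)

    records: list[FcdRecord] = []
    # one reconstruction per transition, vectorized over clusters
    y_cols = []
    for t_lab in transitions:
        tips = pd.DataFrame(
            {
                sp: fold_changes_by_species[sp][t_lab].to_numpy(dtype=float)
                for sp in tree.leaf_names
            },
            index=clusters,
        )
        est = bm_reconstruct(tree, tips)
        y_cols.append(node_lookup(est, node_name, tree=tree))
    y = np.column_stack(y_cols)  # clusters x transitions
    x = ref.loc[clusters, transitions].to_numpy(dtype=float)

    for i, cid in enumerate(clusters):
        gene = scog_map.member(cid, focal_species)
        records.append(fcd(x[i], y[i], cluster_id=cid, gene_id=gene, scale=scale))
    return rank_clusters(records)
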