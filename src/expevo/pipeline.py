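"""End-to-end analysis: activity filter -> fold changes -> ancestral
reconstruction -> FCD ranking, and the divergence comparison."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .activity import call_activity, filter_scogs, z_transform
from .divergence import DivergenceRecord, GroupComparison, cluster_divergence, compare_groups
from .expression import fold_change_matrix, relative_profile_matrix
from .io import Config, ExpressionMatrix, ScogMap, validate_scog_against
from .ranking import FcdRecord, contrast_against_node
from .tree import PhyloTree


@dataclass(frozen=True)
class PriorityResult:
    records: list[FcdRecord]  # ranked
    retained: ScogMap
    excluded: list[str]
    node_name: str
    focal_species: str


def cluster_fold_changes(
    matrices: dict[str, ExpressionMatrix], scog_map: ScogMap, pseudocount: float
) -> dict[str, pd.DataFrame]:
    """Per-species log2 fold changes re-indexed by cluster id."""
    out = {}
    for sp in scog_map.species:
        fc = fold_change_matrix(matrices[sp], pseudocount)
        members = scog_map.table[sp]
        out[sp] = fc.loc[members].set_axis(scog_map.cluster_ids, axis=0)
    return out


def run_priority_pipeline(
    matrices: dict[str, ExpressionMatrix],
    tree: PhyloTree,
    scog_map: ScogMap,
    focal_species: str,
    node_name: str | None = None,
    config: Config | None = None,
) -> PriorityResult:
    """Rank clusters of a focal species by fold-change differential.

    Steps: per-species z-transform and activity calls; exclusion of clusters
    with any inactive member; log2 fold changes for retained members;
    per-character Brownian-motion reconstruction on the tree; FCD against the
    requested ancestral node (root/MRCA by default); ranked records.
    """
    cfg = config or Config()
    validate_scog_against(scog_map, matrices)
    activity = {
        sp: call_activity(z_transform(m), z_threshold=cfg.z_threshold)
        for sp, m in matrices.items()
    }
    retained, excluded = filter_scogs(scog_map, activity)
    fcs = cluster_fold_changes(matrices, retained, cfg.pseudocount)
    records = contrast_against_node(
        fcs, tree, retained, focal_species, node_name, scale=cfg.fcd_scale
    )
    return PriorityResult(
        records=records,
        retained=retained,
        excluded=excluded,
        node_name=node_name or tree.root_name,
        focal_species=focal_species,
    )


@dataclass(frozen=True)
class DivergenceResult:
    records: list[DivergenceRecord]  # pooled (all species pairs)
    pooled: GroupComparison
    per_species: dict[str, GroupComparison]


def run_divergence_analysis(
    matrices: dict[str, ExpressionMatrix],
    scog_map: ScogMap,
    flags: dict[str, bool],
    min_functional: int = 2,
) -> DivergenceResult:
    """Cluster expression divergence and the hypothetical-vs-functional test.

    Emits the pooled comparison (distances averaged over all species pairs)
    and one comparison per focal species (pairs involving that species).
    ``scog_map`` should already be restricted to actively transcribed
    clusters so every member has a nonzero profile.
    """
    profiles = {}
    for sp, m in matrices.items():
        members = list(scog_map.table[sp])
        sub = ExpressionMatrix(species=sp, data=m.data.loc[members])
        profiles[sp] = relative_profile_matrix(sub)
    pooled_records = cluster_divergence(profiles, scog_map, flags, min_functional)
    per_species = {}
    for sp in scog_map.species:
        recs = cluster_divergence(
            profiles, scog_map, flags, min_functional, focal_species=sp
        )
        per_species[sp] = compare_groups(recs)
    return DivergenceResult(
        records=pooled_records,
        pooled=compare_groups(pooled_records),
        per_species=per_species,
    )
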