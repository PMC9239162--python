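"""Expression divergence of ortholog clusters and the functional/hypothetical
group comparison.

Divergence of one cluster is the mean Euclidean distance between the
species' relative expression profiles (points on the stage simplex), taken
over all unordered species pairs — bounded by [0, sqrt(2)], the simplex
diameter. Clusters with at least ``min_functional`` members carrying a
predicted protein domain are "functional", the rest "hypothetical"; the two
groups' divergence distributions are compared by a Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .io import ScogMap

SIMPLEX_TOL = 1e-6
EXACT_MAX_NM = 100_000  # exact U distribution when n*m at or below this


@dataclass(frozen=True)
class DivergenceRecord:
    cluster_id: str
    mean_euclid: float
    class_label: str | None = None  # "functional" | "hypothetical"


@dataclass(frozen=True)
class RankSumResult:
    U: float
    p_value: float
    method: str  # "exact" | "normal_approx"

    def __post_init__(self):
        if not (0 < self.p_value <= 1 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _check_simplex(profiles: np.ndarray) -> None:
    if (profiles < -SIMPLEX_TOL).any():
        raise ValueError("profile has negative entries")
    if np.abs(profiles.sum(axis=1) - 1.0).max() > SIMPLEX_TOL:
        raise ValueError("profile does not lie on the simplex (sum != 1)")


def pairwise_mean_euclid(
    profiles: dict[str, np.ndarray], focal_species: str | None = None
) -> float:
    """Mean Euclidean distance over species pairs of simplex profiles.

    With ``focal_species`` given, only the pairs involving that species are
    averaged (the per-species view of divergence); otherwise all C(k, 2)
    unordered pairs.
    """
    species = list(profiles)
    if len(species) < 2:
        raise ValueError("need profiles from at least two species")
    mat = np.vstack([np.asarray(profiles[sp], dtype=float) for sp in species])
    _check_simplex(mat)
    d = squareform(pdist(mat))
    if focal_species is None:
        iu = np.triu_indices(len(species), k=1)
        return float(d[iu].mean())
    if focal_species not in profiles:
        raise KeyError(f"no profile for focal species {focal_species!r}")
    i = species.index(focal_species)
    others = [j for j in range(len(species)) if j != i]
    return float(d[i, others].mean())


def classify_scog(member_flags, min_functional: int = 2) -> str:
    """"functional" iff at least ``min_functional`` members carry a domain."""
    flags = list(member_flags)
    if not flags:
        raise ValueError("no member flags")
    return "functional" if sum(bool(f) for f in flags) >= min_functional else "hypothetical"


def mann_whitney_u(x, y) -> RankSumResult:
    """Two-sided Mann-Whitney U (midranks, tie-corrected).

    Exact null distribution when the comparison is small (n*m <= 1e5) and
    tie-free; otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= EXACT_MAX_NM and not has_ties:
        method = "exact"
    else:
        method = "normal_approx"
    res = mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(U=float(res.statistic), p_value=float(res.pvalue), method=method)


def cluster_divergence(
    profiles_by_species: dict[str, pd.DataFrame],
    scog_map: ScogMap,
    flags: dict[str, bool],
    min_functional: int = 2,
    focal_species: str | None = None,
) -> list[DivergenceRecord]:
    """Divergence record (with class label) for every cluster in the map.

    ``profiles_by_species``: species -> genes x stages simplex profiles
    (rows indexed by gene id).
    """
    records = []
    for cid in scog_map.cluster_ids:
        prof = {}
        member_flags = []
        for sp in scog_map.species:
            gene = scog_map.member(cid, sp)
            prof[sp] = profiles_by_species[sp].loc[gene].to_numpy(dtype=float)
            if gene not in flags:
                raise KeyError(f"no annotation flag for gene {gene!r}")
            member_flags.append(flags[gene])
        records.append(
            DivergenceRecord(
                cluster_id=cid,
                mean_euclid=pairwise_mean_euclid(prof, focal_species=focal_species),
                class_label=classify_scog(member_flags, min_functional),
            )
        )
    return records


@dataclass(frozen=True)
class GroupComparison:
    test: RankSumResult
    n_functional: int
    n_hypothetical: int
    mean_functional: float
    mean_hypothetical: float
    median_functional: float
    median_hypothetical: float


def compare_groups(records: list[DivergenceRecord]) -> GroupComparison:
    """Rank-sum comparison of hypothetical vs functional cluster divergence."""
    hyp = np.array([r.mean_euclid for r in records if r.class_label == "hypothetical"])
    fun = np.array([r.mean_euclid for r in records if r.class_label == "functional"])
    if hyp.size == 0 or fun.size == 0:
        raise ValueError("both classes must be represented")
    test = mann_whitney_u(hyp, fun)
    return GroupComparison(
        test=test,
        n_functional=int(fun.size),
        n_hypothetical=int(hyp.size),
        mean_functional=float(fun.mean()),
        mean_hypothetical=float(hyp.mean()),
        median_functional=float(np.median(fun)),
        median_hypothetical=float(np.median(hyp)),
    )
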