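"""Per-stage expression estimates, simplex profiles and log2 fold changes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, transition_label

SIMPLEX_TOL = 1e-9


def rpkm_from_counts(counts, gene_length_bp, mapped_reads) -> np.ndarray:
    """RPKM = reads / (transcript kb x million mapped reads).

    All three arguments broadcast; counts must be >= 0, lengths and library
    sizes strictly positive.
    """
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(mapped_reads, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative read count")
    if (length <= 0).any():
        raise ValueError("gene length must be positive")
    if (lib <= 0).any():
        raise ValueError("mapped-read total must be positive")
    return counts / ((length / 1e3) * (lib / 1e6))


class PoissonFit(NamedTuple):
    """Rank-1 Poisson ML fit: expression a_g per gene, effort b_r per replicate."""

    a: np.ndarray  # per-gene expression estimate, scale of one replicate
    b: np.ndarray  # per-replicate relative effort, sums to n_replicates


def poisson_point_estimates(replicate_counts) -> PoissonFit:
    """ML point estimates under count[g, r] ~ Poisson(a_g * b_r).

    With the identifiability constraint sum(b) = number of replicates, the
    ML solution is closed form (the iterative-proportional-fitting fixed
    point): a_g = rowsum_g / sum(b), b_r = colsum_r / total * n_replicates.
    The fitted means a_g * b_r reproduce row and column sums exactly. This
    is the point-estimate core of hierarchical expression-level models: the
    pipeline downstream consumes only single values per gene per stage.
    """
    counts = np.atleast_2d(np.asarray(replicate_counts, dtype=float))
    if (counts < 0).any():
        raise ValueError("negative count")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count matrix")
    n_rep = counts.shape[1]
    b = counts.sum(axis=0) / total * n_rep
    a = counts.sum(axis=1) / n_rep
    return PoissonFit(a=a, b=b)


@dataclass(frozen=True)
class RelativeProfile:
    """Per-gene relative expression across stages: a point on the simplex."""

    gene_id: str
    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if (p < 0).any():
            raise ValueError(f"{self.gene_id}: negative profile entry")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.gene_id}: profile does not sum to 1")
        object.__setattr__(self, "p", p)


def relative_profile(expr, gene_id: str = "") -> RelativeProfile:
    """Normalize nonnegative stage expression to sum to 1."""
    expr = np.asarray(expr, dtype=float)
    if (expr < 0).any():
        raise ValueError("negative expression value")
    s = expr.sum()
    if s <= 0:
        raise ValueError("all-zero expression vector has no relative profile")
    return RelativeProfile(gene_id=gene_id, p=expr / s)


@dataclass(frozen=True)
class FoldChangeProfile:
    """log2 fold changes across adjacent stage transitions t = 0..S-2."""

    gene_id: str
    species: str
    delta: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        if not np.isfinite(d).all():
            raise ValueError(f"{self.gene_id}: non-finite fold change")
        object.__setattr__(self, "delta", d)

    @property
    def n_transitions(self) -> int:
        return self.delta.size


def log_fold_changes(
    expr, pseudocount: float = 1.0, gene_id: str = "", species: str = ""
) -> FoldChangeProfile:
    """delta[t] = log2((expr[t+1] + eps) / (expr[t] + eps)) for adjacent stages.

    The pseudocount guards stage-level zeros; with pseudocount 0 any zero
    stage is an error.
    """
    expr = np.asarray(expr, dtype=float)
    if (expr < 0).any():
        raise ValueError("negative expression value")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = expr + pseudocount
    if (shifted == 0).any():
        raise ValueError("zero expression with zero pseudocount")
    delta = np.log2(shifted[1:]) - np.log2(shifted[:-1])
    return FoldChangeProfile(gene_id=gene_id, species=species, delta=delta)


# ---------------------------------------------------------------------------
# whole-matrix conveniences used by the pipeline
# ---------------------------------------------------------------------------


def fold_change_matrix(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Genes x transitions DataFrame of log2 fold changes for one species."""
    expr = matrix.data.to_numpy(dtype=float) + pseudocount
    if (expr <= 0).any():
        raise ValueError("zero expression with zero pseudocount")
    logs = np.log2(expr)
    delta = logs[:, 1:] - logs[:, :-1]
    cols = [transition_label(t) for t in range(matrix.data.shape[1] - 1)]
    return pd.DataFrame(delta, index=matrix.data.index, columns=cols)


def relative_profile_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Genes x stages DataFrame of simplex profiles (rows sum to 1)."""
    expr = matrix.data.to_numpy(dtype=float)
    sums = expr.sum(axis=1)
    if (sums <= 0).any():
        gene = matrix.data.index[int(np.argmax(sums <= 0))]
        raise ValueError(f"all-zero expression for gene {gene!r}")
    return pd.DataFrame(
        expr / sums[:, None], index=matrix.data.index, columns=matrix.data.columns
    )
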