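"""Maximum-likelihood ancestral states of continuous characters under
Brownian motion on a rooted tree.

Under BM a character changes along each branch by Normal(0, sigma^2 * length).
The ML root state is the generalized-least-squares estimate

    y_hat = (1' V^-1 1)^-1 1' V^-1 x,      V[i, j] = shared root-to-MRCA path,

and the ML internal-node states minimize sum over edges of
(x_parent - x_child)^2 / length with the tip values fixed. Both are computed
here in linear time by Gaussian message passing (Felsenstein pruning upward,
a marginalizing pass downward) — dense GLS and a sparse linear solve serve
as independent cross-checks in the test suite, never as the implementation.

Messages carry a vector mean per character and a scalar variance (the
variance depends only on tree geometry), so one pass reconstructs all
characters of a gene set at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import PhyloTree


@dataclass(frozen=True)
class AncestralEstimate:
    """Reconstructed values at every internal node for a set of characters.

    node_values: internal-node names -> array (n_characters,)
    root_variance: per-character estimator variance at the root,
                   (1' V^-1 1)^-1 * sigma2_hat (ML rate, 1/n normalization)
    """

    character_ids: tuple[str, ...]
    node_values: dict[str, np.ndarray]
    root_name: str
    root_variance: np.ndarray
    leaf_names: tuple[str, ...]

    @property
    def root_values(self) -> np.ndarray:
        return self.node_values[self.root_name]


def _check_tip_matrix(tree: PhyloTree, tips: pd.DataFrame) -> np.ndarray:
    missing = [ln for ln in tree.leaf_names if ln not in tips.columns]
    if missing:
        raise ValueError(f"tip value(s) missing for leaf/leaves: {missing}")
    x = tips[list(tree.leaf_names)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite tip value")
    for node in range(tree.n_nodes - 1):
        if tree.branch_lengths[node] <= 0:
            raise ValueError(
                f"non-positive branch length above node {tree.names[node]!r}"
            )
    return x


def bm_reconstruct(tree: PhyloTree, tip_values: pd.DataFrame) -> AncestralEstimate:
    """Reconstruct all internal-node states for many characters at once.

    ``tip_values``: DataFrame, one row per character, one column per leaf
    name. Returns marginal ML states at every internal node plus the root
    estimator variance per character.
    """
    x = _check_tip_matrix(tree, tip_values)  # (n_char, n_leaves)
    n_char = x.shape[0]
    leaf_col = {name: j for j, name in enumerate(tree.leaf_names)}

    # ---- upward pass (pruning): message from each node to its parent ----
    # message i ~ Normal(up_mu[i], up_v[i]) for the subtree below i, seen
    # from just above node i's edge.
    up_mu = np.empty((tree.n_nodes, n_char))
    up_v = np.empty(tree.n_nodes)
    cond_mu = np.empty((tree.n_nodes, n_char))  # combination of child messages
    cond_v = np.empty(tree.n_nodes)

    for node in tree.postorder():
        if tree.is_leaf(node):
            cond_mu[node] = x[:, leaf_col[tree.names[node]]]
            cond_v[node] = 0.0
        else:
            prec = 0.0
            wsum = np.zeros(n_char)
            for c in tree.children[node]:
                p = 1.0 / up_v[c]
                prec += p
                wsum += p * up_mu[c]
            cond_v[node] = 1.0 / prec
            cond_mu[node] = wsum / prec
        up_mu[node] = cond_mu[node]
        up_v[node] = cond_v[node] + tree.branch_lengths[node]

    root = tree.root
    root_var_factor = cond_v[root]  # equals (1' V^-1 1)^-1

    # ---- downward pass: message to each node from the rest of the tree ----
    # down (mu, v) at node i: distribution of node i's state given all data
    # outside i's subtree; at the root it is flat (infinite variance).
    down_mu = np.zeros((tree.n_nodes, n_char))
    down_v = np.full(tree.n_nodes, np.inf)
    marg_mu = np.empty((tree.n_nodes, n_char))

    for node in tree.preorder():
        if np.isinf(down_v[node]):
            marg_mu[node] = cond_mu[node]
        else:
            p_up = 1.0 / cond_v[node] if cond_v[node] > 0 else np.inf
            if np.isinf(p_up):  # leaf: value is data
                marg_mu[node] = cond_mu[node]
            else:
                p_dn = 1.0 / down_v[node]
                marg_mu[node] = (p_up * cond_mu[node] + p_dn * down_mu[node]) / (
                    p_up + p_dn
                )
        for c in tree.children[node]:
            # combine parent-side info with the other children's messages
            if np.isinf(down_v[node]):
                prec = 0.0
                wsum = np.zeros(n_char)
            else:
                prec = 1.0 / down_v[node]
                wsum = prec * down_mu[node]
            for s in tree.children[node]:
                if s == c:
                    continue
                p = 1.0 / up_v[s]
                prec += p
                wsum += p * up_mu[s]
            down_mu[c] = wsum / prec
            down_v[c] = 1.0 / prec + tree.branch_lengths[c]

    # ---- ML rate and root estimator variance ----
    # sigma2_hat = (1/n) (x - y 1)' V^-1 (x - y 1), via independent
    # contrasts accumulated during an extra pruning sweep (Felsenstein).
    sigma2 = _ml_rate(tree, x)
    root_variance = root_var_factor * sigma2

    char_ids = tuple(str(i) for i in tip_values.index)
    node_values = {
        tree.names[i]: marg_mu[i].copy() for i in tree.internal_nodes
    }
    return AncestralEstimate(
        character_ids=char_ids,
        node_values=node_values,
        root_name=tree.root_name,
        root_variance=root_variance,
        leaf_names=tree.leaf_names,
    )


def _ml_rate(tree: PhyloTree, x: np.ndarray) -> np.ndarray:
    """Per-character ML Brownian rate via standardized contrasts (1/n norm)."""
    n_char, n_leaves = x.shape
    leaf_col = {name: j for j, name in enumerate(tree.leaf_names)}
    mu = np.empty((tree.n_nodes, n_char))
    v = np.empty(tree.n_nodes)
    ss = np.zeros(n_char)
    for node in tree.postorder():
        if tree.is_leaf(node):
            mu[node] = x[:, leaf_col[tree.names[node]]]
            v[node] = tree.branch_lengths[node]
            continue
        kids = list(tree.children[node])
        # fold children in pairwise; each fold yields one contrast
        m, var = mu[kids[0]], v[kids[0]]
        for c in kids[1:]:
            ss += (m - mu[c]) ** 2 / (var + v[c])
            var_new = var * v[c] / (var + v[c])
            m = (m / var + mu[c] / v[c]) * var_new
            var = var_new
        mu[node] = m
        v[node] = var + tree.branch_lengths[node]
    return ss / n_leaves


# ---------------------------------------------------------------------------
# single-character conveniences (the spec-level operations)
# ---------------------------------------------------------------------------


def _as_frame(tip_values: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame([tip_values], index=["character"])


def bm_root_estimate(tree: PhyloTree, tip_values: dict[str, float]) -> tuple[float, float]:
    """GLS/ML root state and its estimator variance for one character."""
    est = bm_reconstruct(tree, _as_frame(tip_values))
    return float(est.root_values[0]), float(est.root_variance[0])


def bm_internal_states(tree: PhyloTree, tip_values: dict[str, float]) -> AncestralEstimate:
    """ML states at every internal node for one character."""
    return bm_reconstruct(tree, _as_frame(tip_values))


def node_lookup(
    estimate: AncestralEstimate, node_name: str, tree: PhyloTree | None = None
) -> np.ndarray:
    """Reconstructed value(s) at a named internal node.

    Also accepts ``"MRCA:leafA,leafB"`` when the tree is supplied. Leaves are
    data, not estimates, and raise.
    """
    if node_name.startswith("MRCA:"):
        if tree is None:
            raise ValueError("MRCA lookup requires the tree")
        a, b = (s.strip() for s in node_name[len("MRCA:"):].split(","))
        node_name = tree.names[tree.mrca(a, b)]
    if node_name in estimate.leaf_names:
        raise KeyError(f"{node_name!r} is a leaf; leaves are data, not estimates")
    if node_name not in estimate.node_values:
        raise KeyError(
            f"unknown node {node_name!r}; internal nodes: "
            f"{', '.join(estimate.node_values)}"
        )
    return estimate.node_values[node_name]
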