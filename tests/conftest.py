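import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import expevo as ev

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def balanced_tree():
    """((A,B),(C,D)) with unit-ish branch lengths."""
    return ev.parse_newick("((A:1,B:1):0.5,(C:1.5,D:0.5):1);")


@pytest.fixture
def five_taxon_tree():
    return ev.simulate_tree(5, depth=1.0, seed=11)


def dense_gls_root(tree, tip_values):
    """Independent dense-matrix oracle for the BM root state.

    Builds V[i, j] = shared root-to-MRCA path length from scratch and solves
    the GLS normal equations directly.
    """
    leaves = tree.leaf_names
    V = np.empty((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            V[i, j] = tree.depth(tree.mrca(a, b))
    x = np.array([tip_values[l] for l in leaves], dtype=float)
    one = np.ones(len(leaves))
    Vi = np.linalg.inv(V)
    denom = one @ Vi @ one
    return float(one @ Vi @ x / denom), float(1.0 / denom), V


def laplacian_internal_states(tree, tip_values):
    """Independent sparse-system oracle for the internal ML states.

    Minimizes sum over edges of (x_parent - x_child)^2 / length with tips
    fixed, by solving the normal equations of the weighted graph Laplacian.
    """
    internal = list(tree.internal_nodes)
    idx = {n: k for k, n in enumerate(internal)}
    A = np.zeros((len(internal), len(internal)))
    b = np.zeros(len(internal))
    for node in range(tree.n_nodes - 1):  # skip root (no parent edge)
        p = idx[tree.parent[node]]
        w = 1.0 / tree.branch_lengths[node]
        if tree.is_leaf(node):
            A[p, p] += w
            b[p] += w * tip_values[tree.names[node]]
        else:
            c = idx[node]
            A[c, c] += w
            A[p, p] += w
            A[c, p] -= w
            A[p, c] -= w
    sol = np.linalg.solve(A, b)
    return {tree.names[n]: sol[idx[n]] for n in internal}


def random_tree(rng, max_taxa=12):
    n = int(rng.integers(3, max_taxa + 1))
    return ev.simulate_tree(n, depth=float(rng.uniform(0.5, 3.0)), seed=int(rng.integers(2**31)))


@pytest.fixture
def tiny_expression():
    data = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0, 16.0, 32.0], [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2"],
        columns=list(ev.io.DEFAULT_STAGES),
    )
    return ev.ExpressionMatrix(species="spX", data=data)
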