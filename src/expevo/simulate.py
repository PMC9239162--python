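"""Synthetic five-species developmental transcriptome generator.

Emulates the data structure of a comparative perithecium-development study:
five species on a rooted ultrametric tree, six developmental stages, and for
every single-copy ortholog cluster a vector of five log2 fold changes
(stage transitions) that evolves along the tree under Brownian motion. On
top of that neutral backbone the generator plants

* lineage-specific activation shifts (+delta log2 at one transition on one
  terminal branch) in a small minority of genes — the signal the
  fold-change-differential ranking is meant to recover;
* silent genes (near-zero RPKM everywhere) that the activity filter must
  exclude;
* a "hypothetical" gene class evolving at a multiple of the base rate, with
  no protein-domain flags — reproducing the divergence contrast
  qualitatively.

Counts are Poisson around RPKM x length_kb x library-millions and mapped
back to observed RPKM, so the emitted tables carry realistic sampling noise.
A truth object records everything planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    ScogMap,
    write_annotation_flags,
    write_expression_table,
    write_scog_map,
)
from .tree import PhyloTree, parse_newick


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults mirror the structure of the emulated study: 5 species, 6
    stages, ~2,000 expressed ortholog clusters, unit-depth tree with unit
    Brownian rate (log2^2 per unit depth), 25 planted +4 log2 activation
    shifts on the focal terminal branch at the first transition, 2% silent
    genes, 10% hypothetical-class (domain-less) genes, log2 baseline
    expression ~ Normal(4, 2^2), ~1.5 kb genes, 10 M mapped reads. The
    hypothetical class evolves at ``rate_multiplier`` x the base rate
    (1 by default; set 4 to plant the divergence contrast).
    """

    n_species: int = 5
    n_stages: int = 6
    n_genes: int = 2000
    tree_newick: str | None = None  # simulated when None
    tree_depth: float = 1.0
    bm_rate: float = 1.0  # sigma^2, log2^2 per unit branch length
    rate_multiplier: float = 1.0  # extra rate for hypothetical-class genes
    fraction_hypothetical: float = 0.10
    n_planted: int = 25
    shift: float = 4.0  # delta, log2 units
    planted_species: str | None = None  # default: first leaf
    planted_transition: int = 0
    fraction_silent: float = 0.02
    baseline_mu: float = 4.0  # log2 RPKM at stage 0
    baseline_sd: float = 2.0
    root_delta_sd: float = 1.0  # spread of ancestral fold changes
    length_log_mean: float = math.log(1500.0)  # gene length ~ LogNormal, bp
    length_log_sd: float = 0.4
    library_size: float = 1e7  # mapped reads per sample
    count_noise: bool = True
    nb_dispersion: float = 0.0  # negative-binomial overdispersion; 0 = Poisson
    seed: int = 42

    def __post_init__(self):
        if self.n_species < 2 or self.n_stages < 2:
            raise ValueError("need >= 2 species and >= 2 stages")
        if not (0 <= self.fraction_silent < 1):
            raise ValueError("fraction_silent must be in [0, 1)")
        if not (0 <= self.fraction_hypothetical <= 1):
            raise ValueError("fraction_hypothetical must be in [0, 1]")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")
        if min(self.bm_rate, self.rate_multiplier, self.shift * 0 + 1) < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.planted_transition <= self.n_stages - 2):
            raise ValueError("planted_transition out of range")


@dataclass(frozen=True)
class SyntheticTruth:
    """What was planted: per-gene labels and true fold changes per node."""

    genes: pd.DataFrame  # index cluster_id: planted, class_label, silent, ...
    node_deltas: dict[str, np.ndarray]  # node name -> (n_genes, n_transitions)

    def planted_clusters(self) -> list[str]:
        return list(self.genes.index[self.genes["planted"]])


@dataclass(frozen=True)
class SyntheticDataset:
    config: SimConfig
    tree: PhyloTree
    matrices: dict[str, ExpressionMatrix]
    scog_map: ScogMap
    flags: dict[str, bool]
    truth: SyntheticTruth

    @property
    def focal_species(self) -> str:
        """The leaf carrying the planted activation shifts."""
        return self.config.planted_species or self.tree.leaf_names[0]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n", encoding="utf-8")
        for sp, mat in self.matrices.items():
            write_expression_table(mat, out / f"expression_{sp}.tsv")
        write_scog_map(self.scog_map, out / "scogs.tsv")
        write_annotation_flags(self.flags, out / "flags.tsv")
        truth = self.truth.genes.copy()
        truth.index.name = "cluster_id"
        truth.to_csv(out / "truth.tsv", sep="\t")


def simulate_tree(n_species: int, depth: float = 1.0, seed: int = 0) -> PhyloTree:
    """Random rooted bifurcating ultrametric tree with root-to-leaf = depth.

    Coalescent-style: leaves at height 0, n-1 merge events at sorted uniform
    heights rescaled so the root sits exactly at ``depth``. Deterministic
    under the seed.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, depth, size=n_species - 1))
    times = times / times[-1] * depth
    lineages = [(f"sp{i + 1}", 0.0) for i in range(n_species)]
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (sa, ha), (sb, hb) = lineages[i], lineages[j]
        merged = f"({sa}:{t - ha:.10g},{sb}:{t - hb:.10g})"
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append((merged, float(t)))
    return parse_newick(lineages[0][0] + ";")


def evolve_characters(
    tree: PhyloTree,
    root_values: np.ndarray,
    sigma2,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Brownian motion of characters down the tree.

    ``root_values`` has shape (n_char,) or (n_genes, k); ``sigma2`` is a
    scalar or per-character array broadcastable to that shape. Each child
    state is parent + Normal(0, sigma2 * branch_length). Returns a value
    array per node name (tips and internal nodes).
    """
    root_values = np.asarray(root_values, dtype=float)
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), root_values.shape)
    if (sigma2 < 0).any():
        raise ValueError("sigma2 must be >= 0")
    values: dict[int, np.ndarray] = {tree.root: root_values.copy()}
    for node in tree.preorder():
        if node == tree.root:
            continue
        parent = values[tree.parent[node]]
        sd = np.sqrt(sigma2 * tree.branch_lengths[node])
        values[node] = parent + rng.normal(0.0, 1.0, size=parent.shape) * sd
    return {tree.names[i]: v for i, v in values.items()}


def plant_shift(
    tip_values: dict[str, np.ndarray],
    tree: PhyloTree,
    branch: str,
    transition: int,
    delta: float,
    planted_rows: np.ndarray,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Add a lineage-specific activation shift on one terminal branch.

    ``tip_values[leaf]`` is (n_genes, n_transitions); ``delta`` is added at
    ``transition`` for the rows in ``planted_rows`` of the named leaf only.
    Returns (modified copy, boolean planted mask).
    """
    if branch not in tree.leaf_names:
        raise ValueError(f"{branch!r} is not a terminal branch")
    n_genes, n_trans = tip_values[branch].shape
    if not (0 <= transition < n_trans):
        raise ValueError("transition out of range")
    mask = np.zeros(n_genes, dtype=bool)
    mask[np.asarray(planted_rows, dtype=int)] = True
    out = {k: v.copy() for k, v in tip_values.items()}
    out[branch][mask, transition] += delta
    return out, mask


def emit_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset described by ``config``.

    Stage-0 log2 expression is drawn from the baseline distribution (shared
    across species); later stages accumulate each species' evolved fold
    changes. Silent genes get RPKM ~ Uniform(0, 0.05) everywhere. Counts are
    Poisson (optionally negative-binomial) and mapped back to observed RPKM.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_stages - 1

    if cfg.tree_newick is not None:
        tree = parse_newick(cfg.tree_newick)
        if len(tree.leaf_names) != cfg.n_species:
            raise ValueError("tree leaf count does not match n_species")
    else:
        tree = simulate_tree(cfg.n_species, cfg.tree_depth, seed=cfg.seed)
    species = list(tree.leaf_names)
    focal = cfg.planted_species or species[0]

    # gene classes
    n_hyp = int(round(cfg.fraction_hypothetical * cfg.n_genes))
    n_silent = int(round(cfg.fraction_silent * cfg.n_genes))
    perm = rng.permutation(cfg.n_genes)
    hyp_idx = np.sort(perm[:n_hyp])
    silent_idx = np.sort(perm[n_hyp:n_hyp + n_silent])  # disjoint from planted pool
    is_hyp = np.zeros(cfg.n_genes, dtype=bool)
    is_hyp[hyp_idx] = True
    is_silent = np.zeros(cfg.n_genes, dtype=bool)
    is_silent[silent_idx] = True
    planted_pool = np.flatnonzero(~is_silent)
    planted_idx = np.sort(rng.choice(planted_pool, size=cfg.n_planted, replace=False))

    # Brownian evolution of fold-change characters
    rates = np.where(is_hyp, cfg.bm_rate * cfg.rate_multiplier, cfg.bm_rate)
    root_deltas = rng.normal(0.0, cfg.root_delta_sd, size=(cfg.n_genes, T))
    node_deltas = evolve_characters(tree, root_deltas, rates[:, None], rng)
    tip_deltas = {sp: node_deltas[sp] for sp in species}
    tip_deltas, planted_mask = plant_shift(
        tip_deltas, tree, focal, cfg.planted_transition, cfg.shift, planted_idx
    )
    node_deltas = {**node_deltas, **tip_deltas}

    baseline = rng.normal(cfg.baseline_mu, cfg.baseline_sd, size=cfg.n_genes)
    lengths = rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, size=cfg.n_genes)
    scale = (lengths / 1e3) * (cfg.library_size / 1e6)  # RPKM -> expected counts

    cluster_ids = [f"OG{i + 1:05d}" for i in range(cfg.n_genes)]
    matrices: dict[str, ExpressionMatrix] = {}
    scog_cols: dict[str, list[str]] = {}
    flags: dict[str, bool] = {}
    stage_labels = [f"S{s}" for s in range(cfg.n_stages)]

    for sp in species:
        log2e = np.empty((cfg.n_genes, cfg.n_stages))
        log2e[:, 0] = baseline
        log2e[:, 1:] = baseline[:, None] + np.cumsum(tip_deltas[sp], axis=1)
        rpkm = np.exp2(log2e)
        rpkm[is_silent] = rng.uniform(0.0, 0.05, size=(n_silent, cfg.n_stages))
        if cfg.count_noise:
            lam = rpkm * scale[:, None]
            if cfg.nb_dispersion > 0:
                # Gamma-Poisson mixture: Var = lam + dispersion * lam^2
                shape = 1.0 / cfg.nb_dispersion
                lam = rng.gamma(shape, lam / shape)
            counts = rng.poisson(lam)
            rpkm = counts / scale[:, None]
        gene_ids = [f"{sp}_g{i + 1:05d}" for i in range(cfg.n_genes)]
        matrices[sp] = ExpressionMatrix(
            species=sp,
            data=pd.DataFrame(rpkm, index=gene_ids, columns=stage_labels),
        )
        scog_cols[sp] = gene_ids
        for i, g in enumerate(gene_ids):
            flags[g] = not is_hyp[i]

    scog = ScogMap(pd.DataFrame(scog_cols, index=pd.Index(cluster_ids, name="cluster_id")))

    genes = pd.DataFrame(
        {
            "planted": planted_mask,
            "planted_species": np.where(planted_mask, focal, ""),
            "planted_transition": np.where(planted_mask, cfg.planted_transition, -1),
            "class_label": np.where(is_hyp, "hypothetical", "functional"),
            "silent": is_silent,
        },
        index=pd.Index(cluster_ids, name="cluster_id"),
    )
    truth = SyntheticTruth(genes=genes, node_deltas=node_deltas)
    return SyntheticDataset(
        config=cfg, tree=tree, matrices=matrices, scog_map=scog, flags=flags, truth=truth
    )
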