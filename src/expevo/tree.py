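"""Rooted species phylogeny with positive branch lengths.

Wraps dendropy's Newick machinery in a small immutable structure indexed by
node id, with deterministic auto-naming of unnamed internal nodes so that any
ancestor (e.g. the common ancestor of two named species) is addressable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

DEFAULT_BRANCH_EPSILON = 1e-8


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, missing lengths, ...)."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a pipeline invariant."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree stored as parallel arrays indexed by node id.

    Node ids are assigned in post-order (children before parents), so the
    root is always the last id. ``branch_lengths[i]`` is the length of the
    edge from node ``i`` to its parent; it is ``0.0`` for the root and
    strictly positive everywhere else (zero-length input edges are floored
    to a small epsilon at parse time).
    """

    names: tuple[str, ...]
    parent: tuple[int, ...]  # -1 for the root
    children: tuple[tuple[int, ...], ...]
    branch_lengths: tuple[float, ...]

    # derived lookups
    _index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    # ---- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_name(self) -> str:
        return self.names[self.root]

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaves(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_nodes) if self.is_leaf(i))

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.leaves)

    @property
    def internal_nodes(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_nodes) if not self.is_leaf(i))

    @property
    def internal_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.internal_nodes)

    def node_id(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"unknown node {name!r}; available nodes: {', '.join(self.names)}"
            ) from None

    def postorder(self) -> range:
        # post-order by construction
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    # ---- queries ---------------------------------------------------------

    def depth(self, node: int) -> float:
        """Path length from the root down to ``node``."""
        d = 0.0
        while self.parent[node] != -1:
            d += self.branch_lengths[node]
            node = self.parent[node]
        return d

    def ancestors(self, node: int) -> list[int]:
        out = []
        while node != -1:
            out.append(node)
            node = self.parent[node]
        return out

    def mrca(self, name_a: str, name_b: str) -> int:
        """Most recent common ancestor of two named nodes."""
        anc_a = set(self.ancestors(self.node_id(name_a)))
        node = self.node_id(name_b)
        while node not in anc_a:
            node = self.parent[node]
        return node

    # ---- serialisation ---------------------------------------------------

    def to_newick(self) -> str:
        """Canonical Newick: all nodes named, lengths in repr precision."""

        def fmt(x: float) -> str:
            return format(x, ".12g")

        def rec(node: int) -> str:
            if self.is_leaf(node):
                s = self.names[node]
            else:
                inner = ",".join(rec(c) for c in self.children[node])
                s = f"({inner}){self.names[node]}"
            if self.parent[node] != -1:
                s += f":{fmt(self.branch_lengths[node])}"
            return s

        return rec(self.root) + ";"


def parse_newick(
    text: str,
    *,
    require_lengths: bool = True,
    epsilon: float = DEFAULT_BRANCH_EPSILON,
) -> PhyloTree:
    """Parse a rooted Newick string into a validated :class:`PhyloTree`.

    Zero-length branches are floored to ``epsilon`` (with a warning);
    negative lengths are rejected. Unnamed internal nodes receive
    deterministic names ``N1..Nk`` in post-order, so the root of a
    five-species tree with three unnamed deeper nodes is ``N4``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "same taxa" in str(exc):
            raise TreeValidationError(f"duplicate leaf name in Newick: {exc}") from exc
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc

    dnodes = list(dtree.postorder_node_iter())
    if len(dnodes) < 2:
        raise TreeValidationError("tree must contain at least two nodes")

    leaf_seen: set[str] = set()
    auto = 0
    names: list[str] = []
    node_pos: dict[int, int] = {}
    parent: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    floored = 0

    for pos, nd in enumerate(dnodes):
        node_pos[id(nd)] = pos
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeValidationError("leaf without a name")
            name = nd.taxon.label
            if name in leaf_seen:
                raise TreeValidationError(f"duplicate leaf name {name!r}")
            leaf_seen.add(name)
        else:
            name = nd.label
            if not name:
                auto += 1
                name = f"N{auto}"
        names.append(name)
        children.append([node_pos[id(c)] for c in nd.child_nodes()])
        el = nd.edge.length
        if nd.parent_node is None:
            lengths.append(0.0)
        else:
            if el is None:
                if require_lengths:
                    raise NewickParseError(
                        f"missing branch length on edge above node {name!r}"
                    )
                el = epsilon
            if el < 0:
                raise TreeValidationError(
                    f"negative branch length {el} above node {name!r}"
                )
            if el == 0:
                el = epsilon
                floored += 1
            lengths.append(float(el))
        parent.append(-1)

    for pos, nd in enumerate(dnodes):
        for c in children[pos]:
            parent[c] = pos

    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise TreeValidationError(f"duplicate node names: {dup}")

    if floored:
        logger.warning("floored %d zero-length branches to epsilon=%g", floored, epsilon)

    return PhyloTree(
        names=tuple(names),
        parent=tuple(parent),
        children=tuple(tuple(c) for c in children),
        branch_lengths=tuple(lengths),
    )
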