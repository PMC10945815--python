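"""Phylogeny input/output and tree-derived matrices.

Wraps a rooted :class:`dendropy.Tree` in a small, validated container and
derives the two matrices the comparative statistics need:

* the **patristic distance matrix** — for tips *i*, *j*, the sum of branch
  lengths along the path i → MRCA(i, j) → j, in the tree's branch-length
  units (here, expected substitutions per site);
* the **Brownian covariance matrix** — for tips *i*, *j*, the total branch
  length shared on the root-to-tip paths, i.e. the root-to-MRCA depth.
  Under a unit-rate Brownian motion this is exactly Cov(x_i, x_j).

Trees are read and written as Newick (plain or gzip-compressed). The Newick
dialect is deliberately narrow: unquoted labels without whitespace; internal
node labels are ignored; missing branch lengths default to 0.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "patristic_distance_matrix",
    "brownian_covariance",
    "prune_to_representatives",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or validated."""


class Phylogeny:
    """A rooted phylogeny with unique tip labels and nonnegative branch lengths.

    Thin wrapper around :class:`dendropy.Tree`; construction validates the
    invariants (label uniqueness, branch-length sign) once so downstream code
    can rely on them.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._validate()
        self._tip_index: dict[str, dendropy.Node] = {
            leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
        }

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        labels: list[str] = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickParseError("unlabeled tip in tree")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(
                f"duplicate tip labels: {sorted(dupes)}"
            )
        for edge in self._tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {edge.length} above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
        # the root edge carries no information; zero it for clean depths
        self._tree.seed_node.edge.length = 0.0

    # -- basic queries -------------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in the tree's leaf-iteration order."""
        return list(self._tip_index)

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def _require_tips(self, labels: Sequence[str]) -> list[dendropy.Node]:
        missing = [l for l in labels if l not in self._tip_index]
        if missing:
            raise KeyError(f"labels not found in tree: {missing}")
        return [self._tip_index[l] for l in labels]

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- serialisation -------------------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips})"


def read_newick(source: str | Path) -> Phylogeny:
    """Parse a Newick string, file path, or ``.gz`` file path into a Phylogeny.

    Raises :class:`NewickParseError` on malformed input or duplicate tip
    labels.
    """
    text = _resolve_newick_text(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def _resolve_newick_text(source: str | Path) -> str:
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source and Path(source).exists()
    ):
        path = Path(source)
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                return fh.read()
        return path.read_text()
    return str(source)


def write_newick(tree: Phylogeny, path: str | Path | None = None) -> str:
    """Serialise to Newick; optionally write to ``path`` (gzip if ``.gz``)."""
    text = tree.to_newick()
    if path is not None:
        path = Path(path)
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            path.write_text(text)
    return text


def patristic_distance_matrix(
    tree: Phylogeny, labels: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Pairwise path-length distances between tips.

    Returns ``(labels, matrix)`` with a symmetric, zero-diagonal matrix whose
    (i, j) entry is the sum of branch lengths on the path connecting tips
    ``labels[i]`` and ``labels[j]`` through their most recent common ancestor.
    """
    if labels is None:
        labels = tree.tip_labels
    tree._require_tips(labels)
    depth, _ = _node_depths(tree)
    n = len(labels)
    out = np.zeros((n, n))
    nodes = [tree._tip_index[l] for l in labels]
    for i in range(n):
        for j in range(i + 1, n):
            mrca = _mrca(nodes[i], nodes[j], depth)
            d = depth[id(nodes[i])] + depth[id(nodes[j])] - 2.0 * depth[id(mrca)]
            out[i, j] = out[j, i] = d
    return list(labels), out


def brownian_covariance(
    tree: Phylogeny, labels: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Unit-rate Brownian-motion covariance matrix among tips.

    Entry (i, j) is the root-to-MRCA depth of tips i and j (their shared
    evolutionary history); the diagonal is the root-to-tip depth. The matrix
    is symmetric positive semi-definite by construction.
    """
    if labels is None:
        labels = tree.tip_labels
    tree._require_tips(labels)
    depth, _ = _node_depths(tree)
    n = len(labels)
    out = np.zeros((n, n))
    nodes = [tree._tip_index[l] for l in labels]
    for i in range(n):
        out[i, i] = depth[id(nodes[i])]
        for j in range(i + 1, n):
            mrca = _mrca(nodes[i], nodes[j], depth)
            out[i, j] = out[j, i] = depth[id(mrca)]
    return list(labels), out


def _node_depths(tree: Phylogeny) -> tuple[dict[int, float], dict[int, int]]:
    """Root-to-node path length and topological level for every node."""
    depth: dict[int, float] = {}
    level: dict[int, int] = {}
    for node in tree._tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[id(node)] = 0.0
            level[id(node)] = 0
        else:
            depth[id(node)] = depth[id(parent)] + (node.edge.length or 0.0)
            level[id(node)] = level[id(parent)] + 1
    return depth, level


def _mrca(a: dendropy.Node, b: dendropy.Node, depth: Mapping[int, float]) -> dendropy.Node:
    seen = set()
    node = a
    while node is not None:
        seen.add(id(node))
        node = node.parent_node
    node = b
    while id(node) not in seen:
        node = node.parent_node
    return node


def prune_to_representatives(
    tree: Phylogeny,
    mapping: Mapping[str, str],
    representatives: Mapping[str, str] | None = None,
) -> Phylogeny:
    """Collapse a strain-level tree to one tip per population.

    ``mapping`` sends tip (strain) labels to population names. For each
    population one representative strain is kept — by default the
    lexicographically first mapped strain, overridable via ``representatives``
    (population → strain) — and relabeled with the population name.
    Suppressed unifurcations merge their branch lengths, so patristic
    distances among the retained representatives are unchanged.
    """
    populations: dict[str, list[str]] = {}
    for strain, pop in mapping.items():
        populations.setdefault(pop, []).append(strain)
    if representatives is None:
        representatives = {pop: sorted(strains)[0] for pop, strains in populations.items()}
    else:
        for pop, rep in representatives.items():
            if pop not in populations:
                raise ValueError(f"population {pop!r} has no mapped strains")
            if rep not in populations[pop]:
                raise ValueError(f"representative {rep!r} is not mapped to population {pop!r}")
    empty = [p for p, s in populations.items() if not s]
    if empty:
        raise ValueError(f"populations with zero mapped tips: {empty}")
    tree._require_tips(list(representatives.values()))

    keep = set(representatives.values())
    clone = tree._tree.clone(depth=1)
    taxa = [leaf.taxon for leaf in clone.leaf_node_iter() if leaf.taxon.label in keep]
    clone.retain_taxa(taxa)
    # relabel strains with their population names
    strain_to_pop = {rep: pop for pop, rep in representatives.items()}
    for leaf in clone.leaf_node_iter():
        leaf.taxon.label = strain_to_pop[leaf.taxon.label]
    return Phylogeny(clone)
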