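"""Rooted phylogenies and the time/epoch/regime structures the likelihood needs.

A tree is stored in preorder arrays: node 0 is the root, every other node
carries the length of the branch above it. ``node_time`` is the distance from
the root, so a tip's ``node_time`` is its total evolutionary time ``T_i``.
Regimes (selective optima) are painted on branches, each branch identified by
the label of its child node.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "LineageEpochs",
    "SharedTimeMatrix",
    "RegimePainting",
    "read_newick",
    "lineage_epochs",
    "shared_time_matrix",
    "paint_regimes",
    "paint_clades",
    "scale_branches",
    "read_regime_file",
    "single_regime",
    "nine_taxon_tree_newick",
    "nine_taxon_tree",
    "two_subgenus_clades",
    "three_group_clades",
]


class TreeError(ValueError):
    """Raised for structurally invalid trees or paintings."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree with branch lengths, in preorder node arrays.

    Attributes
    ----------
    labels : list of str
        Node labels indexed by node id; node 0 is the root. Unlabeled
        internal nodes receive deterministic ``node<preorder-index>`` labels.
    parent : ndarray of int
        Parent node id per node; -1 for the root.
    branch_length : ndarray of float
        Length of the branch above each node; NaN for the root.
    node_time : ndarray of float
        Root-to-node distance; 0 for the root.
    tips : ndarray of int
        Node ids of the tips, in preorder (left-to-right Newick) order.
    """

    labels: list[str]
    parent: np.ndarray
    branch_length: np.ndarray
    node_time: np.ndarray
    tips: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    @property
    def tip_times(self) -> np.ndarray:
        """Root-to-tip times ``T_i`` in tip order."""
        return self.node_time[self.tips]

    @property
    def depth(self) -> float:
        """Maximum root-to-tip time."""
        return float(self.tip_times.max())

    def label_to_node(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def path_to_root(self, node: int) -> list[int]:
        """Node ids from ``node`` up to (and including) the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[int(self.parent[i])].append(i)
        return ch

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        t = self.tip_times
        return bool(np.allclose(t, t[0], rtol=rtol, atol=rtol * max(1.0, t[0])))

    def to_newick(self) -> str:
        ch = self.children()

        def rec(i: int) -> str:
            if not ch[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(rec(c) for c in ch[i]) + ")" + (
                    self.labels[i] if not self.labels[i].startswith("node") else ""
                )
            if self.parent[i] >= 0:
                s += f":{self.branch_length[i]:.10g}"
            return s

        return rec(0) + ";"


@dataclass(frozen=True)
class LineageEpochs:
    """Per-tip speciation epochs 0 = t_i0 < t_i1 < ... < t_iκ(i) = T_i.

    ``times[i]`` holds the κ(i)+1 epoch boundaries for tip i (tip order);
    ``branch_nodes[i]`` the child-node id of the branch covering each of the
    κ(i) segments (t_iτ−1, t_iτ].
    """

    times: list[np.ndarray]
    branch_nodes: list[np.ndarray]

    def kappa(self, i: int) -> int:
        return len(self.branch_nodes[i])


@dataclass(frozen=True)
class SharedTimeMatrix:
    """N×N matrix s_ij: root-to-MRCA time of tips i and j; s_ii = T_i."""

    values: np.ndarray
    tip_labels: list[str]


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of each branch (by child node id) to one of R regimes.

    ``root_regime`` is the regime whose W column absorbs the root-state
    weight e^{−αT_i} (by default the regime painted first, i.e. the
    background regime).
    """

    n_regimes: int
    regime_names: list[str]
    branch_regime: np.ndarray  # per node id; -1 for the root
    root_regime: int
    tree: PhyloTree = field(repr=False)

    def regime_of(self, child_label: str) -> str:
        node = self.tree.label_to_node()[child_label]
        return self.regime_names[int(self.branch_regime[node])]


def read_newick(source: str) -> PhyloTree:
    """Parse a rooted Newick tree (string or path) into a :class:`PhyloTree`.

    Branch lengths are required on every non-root edge; polytomies are kept
    as-is. Unlabeled internal nodes receive deterministic preorder labels.
    """
    text = source
    if "(" not in text:  # looks like a path
        with open(source) as fh:
            text = fh.read()
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True, rooting="default-rooted"
    )
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}

    labels: list[str] = []
    parent = np.full(len(nodes), -1, dtype=int)
    blen = np.full(len(nodes), np.nan)
    seen: set[str] = set()
    for i, nd in enumerate(nodes):
        if nd.taxon is not None:
            lab = nd.taxon.label
        elif nd.label:
            lab = nd.label
        else:
            lab = f"node{i}"
        if lab in seen:
            raise TreeError(f"duplicate node label {lab!r}")
        seen.add(lab)
        labels.append(lab)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeError(f"missing branch length above node {lab!r}")
            if nd.edge.length <= 0:
                raise TreeError(f"non-positive branch length above node {lab!r}")
            blen[i] = float(nd.edge.length)

    node_time = np.zeros(len(nodes))
    for i in range(1, len(nodes)):
        node_time[i] = node_time[parent[i]] + blen[i]
    tips = np.array([i for i, nd in enumerate(nodes) if nd.is_leaf()], dtype=int)
    if len(tips) == 0:
        raise TreeError("tree has no tips")
    return PhyloTree(labels, parent, blen, node_time, tips)


def lineage_epochs(tree: PhyloTree) -> LineageEpochs:
    """Speciation epochs t_iτ along each root→tip path."""
    times, branches = [], []
    for tip in tree.tips:
        path = tree.path_to_root(int(tip))[::-1]  # root ... tip
        times.append(tree.node_time[path].copy())  # starts at 0, ends at T_i
        branches.append(np.array(path[1:], dtype=int))
    return LineageEpochs(times, branches)


def shared_time_matrix(tree: PhyloTree) -> SharedTimeMatrix:
    """s_ij = node_time of the MRCA of tips i and j (diagonal: T_i)."""
    n = tree.n_tips
    paths = [set(tree.path_to_root(int(t))) for t in tree.tips]
    s = np.zeros((n, n))
    for i in range(n):
        s[i, i] = tree.node_time[tree.tips[i]]
        for j in range(i + 1, n):
            shared = paths[i] & paths[j]
            mrca_time = max(tree.node_time[k] for k in shared)
            s[i, j] = s[j, i] = mrca_time
    return SharedTimeMatrix(s, tree.tip_labels)


def scale_branches(tree: PhyloTree, factor: float) -> PhyloTree:
    """Multiply every branch length by ``factor`` (topology unchanged)."""
    if not factor > 0:
        raise TreeError(f"scale factor must be positive, got {factor}")
    return PhyloTree(
        list(tree.labels),
        tree.parent.copy(),
        tree.branch_length * factor,
        tree.node_time * factor,
        tree.tips.copy(),
    )


def paint_regimes(
    tree: PhyloTree,
    assignment: dict[str, str],
    root_regime: str | None = None,
) -> RegimePainting:
    """Paint every branch with a named regime.

    ``assignment`` maps the branch's child-node label to a regime name and
    must cover all branches. Dense regime indices follow first appearance in
    the mapping; ``root_regime`` defaults to the first-named regime.
    """
    lab2node = tree.label_to_node()
    names: list[str] = []
    branch_regime = np.full(tree.n_nodes, -1, dtype=int)
    for lab, reg in assignment.items():
        if lab not in lab2node:
            raise TreeError(f"assignment names unknown branch (child label {lab!r})")
        if reg not in names:
            names.append(reg)
        branch_regime[lab2node[lab]] = names.index(reg)
    missing = [tree.labels[i] for i in range(1, tree.n_nodes) if branch_regime[i] < 0]
    if missing:
        raise TreeError(f"branches without a regime: {missing}")
    if branch_regime[0] >= 0:
        raise TreeError("the root carries no branch and cannot be painted")
    if root_regime is None:
        root_idx = 0
    else:
        if root_regime not in names:
            raise TreeError(f"root regime {root_regime!r} not among painted regimes")
        root_idx = names.index(root_regime)
    return RegimePainting(len(names), names, branch_regime, root_idx, tree)


def paint_clades(
    tree: PhyloTree,
    clades: list[tuple[set[str], str]],
    background: str = "background",
    root_regime: str | None = None,
) -> RegimePainting:
    """Paint whole clades: each clade (given by its tip set) gets one regime
    on its stem branch and every descendant branch; remaining branches get
    the ``background`` regime. Convenience over :func:`paint_regimes`.
    """
    lab2node = tree.label_to_node()
    ch = tree.children()
    assignment = {tree.labels[i]: background for i in range(1, tree.n_nodes)}
    for tip_set, regime in clades:
        node_paths = [tree.path_to_root(lab2node[t]) for t in tip_set]
        shared = set(node_paths[0])
        for p in node_paths[1:]:
            shared &= set(p)
        mrca = max(shared, key=lambda k: tree.node_time[k])
        stack = [mrca]
        while stack:
            nd = stack.pop()
            if nd != 0:
                assignment[tree.labels[nd]] = regime
            stack.extend(ch[nd])
    if root_regime is None and background in assignment.values():
        root_regime = background
    # ensure background is named first when present
    ordered: dict[str, str] = {}
    for lab, reg in assignment.items():
        if reg == background:
            ordered[lab] = reg
    for lab, reg in assignment.items():
        ordered.setdefault(lab, reg)
    return paint_regimes(tree, ordered, root_regime=root_regime)


def single_regime(tree: PhyloTree, name: str = "global") -> RegimePainting:
    """One regime covering every branch (the constrained, single-optimum case)."""
    return paint_regimes(tree, {tree.labels[i]: name for i in range(1, tree.n_nodes)})


def read_regime_file(path: str, tree: PhyloTree) -> RegimePainting:
    """Read a 2-column CSV regime file.

    Rows are either ``branch_child_label,regime_name`` (per-branch painting)
    or ``tip1|tip2|...,regime_name`` (clade painting; `|`-separated tips).
    The two styles cannot be mixed.
    """
    import csv

    rows: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise TreeError(f"regime file row must have 2 columns: {row}")
            rows.append((row[0].strip(), row[1].strip()))
    if any("|" in key for key, _ in rows):
        clades = [(set(key.split("|")), reg) for key, reg in rows if "|" in key]
        if len(clades) != len(rows):
            raise TreeError("cannot mix per-branch and clade rows in a regime file")
        return paint_clades(tree, clades)
    return paint_regimes(tree, dict(rows))


# ---------------------------------------------------------------------------
# Built-in study trees and paintings

#: Unit-depth ultrametric tree with the nine-species Drosophila study
#: topology: the Sophophora subgenus (dmel,dyak,dana + dpse,dper,dwil) and
#: the Drosophila subgenus (dvir,dmoj,dgri). Split depths are plausible
#: placeholders; rate parameters are interpreted per unit tree depth.
NINE_TAXON_NEWICK = (
    "((((dmel:0.22,dyak:0.22):0.23,dana:0.45):0.35,"
    "((dpse:0.1,dper:0.1):0.45,dwil:0.55):0.25):0.2,"
    "((dvir:0.25,dmoj:0.25):0.25,dgri:0.5):0.5);"
)


def nine_taxon_tree_newick() -> str:
    return NINE_TAXON_NEWICK


def nine_taxon_tree() -> PhyloTree:
    """The unit-depth nine-taxon study-topology tree."""
    return read_newick(NINE_TAXON_NEWICK)


def two_subgenus_clades() -> list[tuple[set[str], str]]:
    """Two-regime painting: Sophophora (background) vs Drosophila subgenus."""
    return [({"dvir", "dmoj", "dgri"}, "drosophila")]


def three_group_clades() -> list[tuple[set[str], str]]:
    """Three equal-size regimes: melanogaster group, obscura+willistoni, Drosophila."""
    return [
        ({"dpse", "dper", "dwil"}, "obscurawil"),
        ({"dvir", "dmoj", "dgri"}, "drosophila"),
    ]
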