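"""Rooted phylogenetic trees, host-parasite association tables, and tree preprocessing.

The in-memory tree is a minimal rooted node structure (labels on leaves,
optional branch lengths, optional bootstrap-style supports on internal
nodes).  Newick parsing is delegated to dendropy; writing is done here so
that output is deterministic (children ordered by their smallest leaf
label), which makes reports diffable.

Preprocessing mirrors what cophylogenetic studies do before reconciling a
parasite tree against its host tree: collapsing weakly supported nodes
into polytomies, and collapsing terminal single-host parasite clades so
that within-host radiations do not masquerade as strings of cospeciations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("cophylokit")

__all__ = [
    "TreeError",
    "NewickParseError",
    "LinksFormatError",
    "Node",
    "PhyloTree",
    "HostParasiteLinks",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "read_tree",
    "write_tree",
    "patristic_distances",
    "collapse_low_support",
    "collapse_terminal_host_clades",
    "read_links",
]


class TreeError(ValueError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class LinksFormatError(ValueError):
    """Malformed host-parasite association table."""


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Leaf name, or an internal node's non-numeric annotation.
    length : float or None
        Length of the branch subtending this node.
    support : float or None
        Support value (0-100 scale) of the clade below this node.
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


@dataclass
class PhyloTree:
    """A rooted tree with uniquely labeled leaves."""

    root: Node

    def __post_init__(self):
        self.validate()

    # -- traversal ----------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def has_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.postorder() if n is not self.root
        )

    def leaf_depths(self) -> dict[str, float]:
        depth: dict[int, float] = {id(self.root): 0.0}
        out = {}
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(
                    f"missing branch length on branch above "
                    f"{node.label or 'an internal node'}"
                )
            depth[id(node)] = depth[id(node.parent)] + node.length
            if node.is_leaf:
                out[node.label] = depth[id(node)]
        if self.n_leaves == 1:
            out = {self.root.label: 0.0} if self.root.is_leaf else out
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = list(self.leaf_depths().values())
        dmax = max(depths)
        return dmax == 0 or (dmax - min(depths)) <= rel_tol * dmax

    # -- validation / copying -----------------------------------------
    def validate(self):
        labels = [n.label for n in self.postorder() if n.is_leaf]
        if any(lab is None for lab in labels):
            raise TreeError("every leaf must be labeled")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} above "
                    f"{node.label or 'an internal node'}"
                )

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def __str__(self):
        return write_newick(self)


# ---------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> tuple[PhyloTree, list[float]]:
    supports: list[float] = []

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            raw = dnode.label
            if raw is not None:
                try:
                    node.support = float(raw)
                    supports.append(node.support)
                except ValueError:
                    node.label = raw
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    return PhyloTree(convert(dtree.seed_node)), supports


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement.

    Internal node labels that parse as numbers are read as supports;
    if every support lies in [0, 1] they are rescaled to the 0-100
    scale with a warning.  Duplicate leaf labels and negative branch
    lengths are rejected.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"malformed Newick: {exc}") from None
    tree, supports = _from_dendropy(dtree)
    if supports and all(0.0 <= s <= 1.0 for s in supports):
        logger.warning("supports in [0, 1] rescaled to the 0-100 scale")
        for node in tree.postorder():
            if node.support is not None:
                node.support *= 100.0
    return tree


def _min_leaf_label(node: Node) -> str:
    while not node.is_leaf:
        node = min(node.children, key=_min_leaf_label)
    return node.label


def _format_float(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick with children ordered by smallest leaf label."""

    def serialize(node: Node) -> str:
        if node.is_leaf:
            out = node.label
        else:
            kids = sorted(node.children, key=_min_leaf_label)
            out = "(" + ",".join(serialize(c) for c in kids) + ")"
            if node.support is not None:
                out += _format_float(node.support)
            elif node.label is not None:
                out += node.label
        if node.length is not None:
            out += f":{_format_float(node.length)}"
        return out

    return serialize(tree.root) + ";"


def read_tree(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(
            self.values[self.labels.index(i), self.labels.index(j)]
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of leaves."""
    leaves = tree.leaves()
    labels = sorted(n.label for n in leaves)
    order = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    # depth of every node, then leaf-pair distance via the LCA:
    # d(i, j) = depth(i) + depth(j) - 2 * depth(lca(i, j))
    depth: dict[int, float] = {id(tree.root): 0.0}
    parent: dict[int, Node] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise TreeError(
                f"missing branch length on branch above "
                f"{node.label or 'an internal node'}"
            )
        depth[id(node)] = depth[id(node.parent)] + node.length
        parent[id(node)] = node.parent

    # leaf sets in postorder accumulate pair distances at their LCA
    below: dict[int, list[Node]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [node]
            continue
        groups = [below.pop(id(c)) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        d = depth[id(a)] + depth[id(b)] - 2 * depth[id(node)]
                        ia, ib = order[a.label], order[b.label]
                        D[ia, ib] = D[ib, ia] = d
        below[id(node)] = [leaf for g in groups for leaf in g]
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------
# Host-parasite association links
# ---------------------------------------------------------------------

@dataclass
class HostParasiteLinks:
    """Binary parasite-by-host association matrix.

    Every parasite (row) must be linked to at least one host.
    """

    parasite_labels: list[str]
    host_labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.parasite_labels), len(self.host_labels)):
            raise ValueError("links matrix shape mismatch")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("links matrix entries must be 0/1")
        if np.any(self.matrix.sum(axis=1) < 1):
            orphans = [
                p
                for p, row in zip(self.parasite_labels, self.matrix)
                if row.sum() < 1
            ]
            raise ValueError(f"parasites without any host link: {orphans}")

    @classmethod
    def from_pairs(cls, pairs) -> "HostParasiteLinks":
        pairs = list(dict.fromkeys(tuple(p) for p in pairs))
        parasites = sorted({p for p, _ in pairs})
        hosts = sorted({h for _, h in pairs})
        A = np.zeros((len(parasites), len(hosts)), dtype=np.int8)
        for p, h in pairs:
            A[parasites.index(p), hosts.index(h)] = 1
        return cls(parasites, hosts, A)

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (p, h)
            for i, p in enumerate(self.parasite_labels)
            for j, h in enumerate(self.host_labels)
            if self.matrix[i, j]
        ]

    def hosts_of(self, parasite: str) -> list[str]:
        i = self.parasite_labels.index(parasite)
        return [h for j, h in enumerate(self.host_labels) if self.matrix[i, j]]

    @property
    def n_links(self) -> int:
        return int(self.matrix.sum())

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("parasite\thost\n")
            for p, h in self.pairs():
                fh.write(f"{p}\t{h}\n")


def read_links(path) -> HostParasiteLinks:
    """Read a two-column parasite<TAB>host table.

    '#'-prefixed lines are comments; a 'parasite	host' header row is
    optional; duplicate rows are deduplicated with a logged warning.
    """
    pairs: list[tuple[str, str]] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise LinksFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            p, h = fields[0].strip(), fields[1].strip()
            if not p or not h:
                raise LinksFormatError(f"{path}: line {lineno}: empty field")
            if lineno == 1 and (p.lower(), h.lower()) == ("parasite", "host"):
                continue
            if (p, h) in seen:
                logger.warning(
                    "%s: line %d: duplicate link %s-%s ignored", path, lineno, p, h
                )
                continue
            seen.add((p, h))
            pairs.append((p, h))
    if not pairs:
        raise LinksFormatError(f"{path}: no association rows found")
    return HostParasiteLinks.from_pairs(pairs)


# ---------------------------------------------------------------------
# Tree preprocessing
# ---------------------------------------------------------------------

def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract internal nodes with support strictly below ``threshold``.

    Nodes without a support value are kept.  The root and leaves are
    never contracted, so the leaf set is unchanged; contracted nodes
    turn their parent into a polytomy.
    """
    out = tree.copy()
    for node in list(out.postorder()):
        if node.is_leaf or node is out.root:
            continue
        if node.support is not None and node.support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children.pop(idx)
            for child in node.children:
                child.parent = parent
                # contracted branch length is absorbed into the children
                if child.length is not None and node.length is not None:
                    child.length += node.length
            parent.children[idx:idx] = node.children
    return PhyloTree(out.root)


def collapse_terminal_host_clades(
    tree: PhyloTree, links: HostParasiteLinks
) -> tuple[PhyloTree, HostParasiteLinks]:
    """Collapse maximal terminal parasite clades tied to a single host.

    Each maximal clade whose leaves all link to exactly one and the same
    host species is replaced by one leaf (the lexicographically first
    member label) carrying that single link.  Repeating the operation is
    a no-op, and the set of distinct (clade, host) associations is
    preserved.
    """
    out = tree.copy()
    for leaf in out.leaves():
        if leaf.label not in links.parasite_labels:
            raise ValueError(f"parasite leaf {leaf.label!r} missing from links")

    # host_set[node] = set of hosts linked below; None marks "mixed"
    host_set: dict[int, frozenset | None] = {}
    for node in out.postorder():
        if node.is_leaf:
            host_set[id(node)] = frozenset(links.hosts_of(node.label))
        else:
            sets = {host_set[id(c)] for c in node.children}
            if None in sets or len(sets) != 1 or len(next(iter(sets))) != 1:
                host_set[id(node)] = None
            else:
                host_set[id(node)] = next(iter(sets))

    def collapse(node: Node) -> None:
        hs = host_set[id(node)]
        if hs is not None and len(hs) == 1 and not node.is_leaf:
            members = sorted(leaf.label for leaf in _subtree_leaves(node))
            node.children = []
            node.label = members[0]
            node.support = None
            return
        for child in node.children:
            collapse(child)

    collapse(out.root)
    out = PhyloTree(out.root)
    kept = set(out.leaf_labels())
    new_pairs = [(p, h) for p, h in links.pairs() if p in kept]
    return out, HostParasiteLinks.from_pairs(new_pairs)


def _subtree_leaves(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.append(cur)
        else:
            stack.extend(cur.children)
    return out
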