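"""Synthetic tanglegrams, trees and alignments with known ground truth.

The cophylogeny generator grows a parasite tree over a given ultrametric
host tree under the four-event model of host-parasite codiversification:
at each host node a parasite lineage either cospeciates (follows both
host daughters) or is sorted (follows one); along host branches the
lineage duplicates (within-host speciation), switches to a contemporaneous
host branch, or dies (a loss), as Poisson events.  Every random decision
is logged, so a simulation can be replayed deterministically and the true
event tally audited against the returned trees.

Defaults emulate a cospeciation-dominated, host-specific parasite
radiation: most host nodes are tracked by the parasite, duplications are
common, switches rare, and losses frequent enough that several host
lineages escape their parasites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .delimit import SeqAlignment
from .trees import HostParasiteLinks, Node, PhyloTree, write_newick

__all__ = [
    "SimParams",
    "SimulatedCophylogeny",
    "simulate_yule",
    "simulate_ddl",
    "simulate_pda",
    "simulate_cophylogeny",
    "replay_cophylogeny",
    "simulate_sequences",
]

EVENT_TYPES = ("cospeciation", "sorting", "duplication", "host_switch")


@dataclass
class SimParams:
    """Parameters of the joint host-parasite history generator.

    p_cosp
        Probability that a parasite lineage cospeciates at a host node.
    r_dup, r_switch, r_loss
        Poisson rates (events per unit branch time) of within-host
        speciation, host-switching, and parasite extinction.
    seq_length, sub_rate, gamma_shape
        Sequence-evolution settings used when alignments are requested.
    """

    p_cosp: float = 0.8
    r_dup: float = 0.5
    r_switch: float = 0.1
    r_loss: float = 0.3
    seq_length: int = 600
    sub_rate: float = 0.05
    gamma_shape: float | None = None

    def __post_init__(self):
        if not 0 <= self.p_cosp <= 1:
            raise ValueError("p_cosp must lie in [0, 1]")
        for name in ("r_dup", "r_switch", "r_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedCophylogeny:
    """A simulated tanglegram with its generating event history."""

    host: PhyloTree
    parasite: PhyloTree
    links: HostParasiteLinks
    tally: dict[str, int]
    events: list[dict]
    draws: list[tuple]
    params: SimParams
    seed: int | None

    def to_files(self, directory) -> None:
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "host.nwk").write_text(write_newick(self.host) + "\n")
        (directory / "parasite.nwk").write_text(write_newick(self.parasite) + "\n")
        self.links.to_tsv(directory / "links.tsv")
        truth = {
            "seed": self.seed,
            "params": {
                "p_cosp": self.params.p_cosp,
                "r_dup": self.params.r_dup,
                "r_switch": self.params.r_switch,
                "r_loss": self.params.r_loss,
            },
            "tally": self.tally,
            "events": self.events,
        }
        (directory / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


# ---------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------

def _grow_birth_tree(n_tips: int, rate_of_k, rng, prefix: str) -> PhyloTree:
    """Grow an ultrametric tree under a k-dependent pure-birth process.

    ``rate_of_k`` maps the current lineage count k to the per-lineage
    speciation rate; the tree is cut at the moment the (n_tips+1)-th
    birth would occur, so the final inter-event interval is included.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    birth_time = {id(root): 0.0}
    t = 0.0
    k = 2
    while True:
        lam = rate_of_k(k)
        if lam <= 0:
            raise ValueError(f"per-lineage rate nonpositive at k={k}")
        t += rng.exponential(1.0 / (k * lam))
        if k == n_tips:
            break
        node = tips.pop(rng.integers(len(tips)))
        birth_time[id(node)] = t
        tips.append(node.add_child(Node()))
        tips.append(node.add_child(Node()))
        k += 1
    present = t
    # assign labels in a reproducible traversal order
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            counter += 1
            node.label = f"{prefix}{counter}"
        stack.extend(reversed(node.children))
    # branch lengths from birth times
    def set_lengths(node: Node, t_node: float):
        for child in node.children:
            t_child = birth_time.get(id(child), present)
            child.length = t_child - t_node
            set_lengths(child, t_child)

    set_lengths(root, 0.0)
    return PhyloTree(root)


def simulate_yule(n_tips: int, lam: float, seed=None, prefix: str = "T") -> PhyloTree:
    """Ultrametric constant-rate pure-birth (Yule) tree with ``n_tips`` tips."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    rng = np.random.default_rng(seed)
    return _grow_birth_tree(n_tips, lambda k: lam, rng, prefix)


def simulate_ddl(
    n_tips: int, lam0: float, K: float, seed=None, prefix: str = "T"
) -> PhyloTree:
    """Diversity-dependent (linear) pure-birth tree: lambda(k) = lam0 (1 - k/K)."""
    if lam0 <= 0 or K <= n_tips:
        raise ValueError("need lam0 > 0 and K > n_tips")
    rng = np.random.default_rng(seed)
    return _grow_birth_tree(n_tips, lambda k: lam0 * (1.0 - k / K), rng, prefix)


def simulate_pda(labels, seed=None) -> PhyloTree:
    """Topology drawn uniformly over all labeled rooted binary topologies.

    Sequential construction: each new leaf attaches to an edge chosen
    uniformly among the 2k-1 edges of the current k-leaf rooted tree
    (counting the root edge), which yields the uniform (PDA,
    proportional-to-distinguishable) distribution.  Branch lengths are
    not assigned.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    rng = np.random.default_rng(seed)
    root = Node()
    root.add_child(Node(labels[0]))
    root.add_child(Node(labels[1]))
    for label in labels[2:]:
        # edges = (parent, child) pairs plus the root edge (None, root)
        edges = [(None, root)]
        stack = [root]
        while stack:
            node = stack.pop()
            for child in node.children:
                edges.append((node, child))
                stack.append(child)
        parent, child = edges[rng.integers(len(edges))]
        mid = Node()
        if parent is None:
            mid.add_child(root)
            mid.add_child(Node(label))
            root = mid
        else:
            idx = parent.children.index(child)
            parent.children[idx] = mid
            mid.parent = parent
            mid.add_child(child)
            mid.add_child(Node(label))
    return PhyloTree(root)


# ---------------------------------------------------------------------
# Joint host-parasite history
# ---------------------------------------------------------------------

class _RngSource:
    """Draws random decisions and logs them for replay."""

    def __init__(self, rng):
        self.rng = rng
        self.log: list[tuple] = []

    def exponential(self, rate: float) -> float:
        x = float(self.rng.exponential(1.0 / rate)) if rate > 0 else np.inf
        self.log.append(("exp", x))
        return x

    def choice(self, n: int, p=None) -> int:
        k = int(self.rng.choice(n, p=p))
        self.log.append(("choice", k))
        return k

    def bernoulli(self, p: float) -> bool:
        b = bool(self.rng.random() < p)
        self.log.append(("bern", b))
        return b


class _PlaybackSource:
    """Replays a recorded decision log."""

    def __init__(self, log):
        self._iter = iter(log)

    def _next(self, kind):
        tag, value = next(self._iter)
        if tag != kind:
            raise ValueError(f"replay log mismatch: expected {kind}, got {tag}")
        return value

    def exponential(self, rate: float) -> float:
        return self._next("exp")

    def choice(self, n: int, p=None) -> int:
        return self._next("choice")

    def bernoulli(self, p: float) -> bool:
        return self._next("bern")


def _host_node_times(host: PhyloTree) -> dict[int, float]:
    if not host.has_lengths():
        raise ValueError("host tree must have branch lengths")
    if not host.is_ultrametric():
        raise ValueError("host tree must be ultrametric")
    times = {id(host.root): 0.0}
    for node in host.preorder():
        if node is not host.root:
            times[id(node)] = times[id(node.parent)] + node.length
    return times


def simulate_cophylogeny(
    host: PhyloTree, params: SimParams | None = None, seed=None
) -> SimulatedCophylogeny:
    """Simulate a parasite tree on ``host`` under the four-event model.

    Raises when every parasite lineage goes extinct before the present;
    callers may retry with a different seed or lower loss rate.
    """
    params = params or SimParams()
    source = _RngSource(np.random.default_rng(seed))
    result = _build(host, params, source)
    parasite, links, tally, events = result
    return SimulatedCophylogeny(
        host=host,
        parasite=parasite,
        links=links,
        tally=tally,
        events=events,
        draws=source.log,
        params=params,
        seed=seed,
    )


def replay_cophylogeny(
    host: PhyloTree, params: SimParams, draws
) -> SimulatedCophylogeny:
    """Re-run a simulation from its recorded decision log."""
    source = _PlaybackSource(draws)
    parasite, links, tally, events = _build(host, params, source)
    return SimulatedCophylogeny(
        host=host,
        parasite=parasite,
        links=links,
        tally=tally,
        events=events,
        draws=list(draws),
        params=params,
        seed=None,
    )


def _host_vertex_names(host: PhyloTree) -> dict[int, str]:
    """Leaves keep their labels; internal vertices are '<minleaf|nleaves>'.

    Matches the vertex naming used in reconciliation reports, so event
    logs and reconciliations refer to host positions the same way.
    """
    names: dict[int, str] = {}
    info: dict[int, tuple[str, int]] = {}
    for node in host.postorder():
        if node.is_leaf:
            info[id(node)] = (node.label, 1)
            names[id(node)] = node.label
        else:
            kids = [info[id(c)] for c in node.children]
            ml = min(k[0] for k in kids)
            nl = sum(k[1] for k in kids)
            info[id(node)] = (ml, nl)
            names[id(node)] = f"<{ml}|{nl}>"
    return names


def _build(host: PhyloTree, params: SimParams, source):
    """Single-pass construction with explicit lineage times."""
    times = _host_node_times(host)
    host_nodes = list(host.preorder())
    edge_label = _host_vertex_names(host)
    tally = {e: 0 for e in EVENT_TYPES}
    events: list[dict] = []
    leaf_hosts: list[str] = []  # host of each parasite leaf, in creation order

    def alive_edges(t: float):
        out = []
        for v in host_nodes:
            if v is host.root:
                continue
            if times[id(v.parent)] < t < times[id(v)]:
                out.append(v)
        return out

    def prune(pnode: Node, t_birth: float) -> Node | None:
        """Suppress unary nodes; returns subtree whose branch starts at t_birth."""
        kids = [c for c in pnode.children if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        pnode.children = []
        for c in kids:
            pnode.add_child(c)
        return pnode

    def at_node(v, t):
        """Returns (subtree_or_None, birth_time_of_subtree_root)."""
        if v.is_leaf:
            leaf = Node(label=f"P{len(leaf_hosts) + 1}")
            leaf_hosts.append(v.label)
            return leaf, t
        if source.bernoulli(params.p_cosp):
            tally["cospeciation"] += 1
            events.append(
                {"type": "cospeciation", "time": t, "host": edge_label[id(v)]}
            )
            subs = [on_edge(hc, t) for hc in v.children]
            return _join(subs, t)
        tally["sorting"] += 1
        side = source.choice(2)
        events.append(
            {"type": "sorting", "time": t, "host": edge_label[id(v)], "side": side}
        )
        return on_edge(v.children[side], t)

    def _join(subs, t_event):
        """Combine child subtrees born at t_event into one internal node."""
        alive = [(node, tb) for node, tb in subs if node is not None]
        if not alive:
            return None, t_event
        if len(alive) == 1:
            return alive[0]
        pnode = Node()
        for node, tb in alive:
            node.length = tb - t_event
            pnode.add_child(node)
        return pnode, t_event

    def on_edge(v, t):
        r_total = params.r_dup + params.r_switch + params.r_loss
        wait = source.exponential(r_total) if r_total > 0 else np.inf
        t_end = times[id(v)]
        if t + wait >= t_end:
            return at_node(v, t_end)
        t_ev = t + wait
        probs = np.array([params.r_dup, params.r_switch, params.r_loss]) / r_total
        kind = source.choice(3, p=probs)
        if kind == 0:
            tally["duplication"] += 1
            events.append(
                {"type": "duplication", "time": t_ev, "host": edge_label[id(v)]}
            )
            subs = [on_edge(v, t_ev), on_edge(v, t_ev)]
            return _join(subs, t_ev)
        if kind == 1:
            targets = [u for u in alive_edges(t_ev) if u is not v]
            if not targets:
                return on_edge(v, t_ev)
            targets.sort(key=lambda u: edge_label[id(u)])
            u = targets[source.choice(len(targets))]
            tally["host_switch"] += 1
            events.append(
                {
                    "type": "host_switch",
                    "time": t_ev,
                    "host": edge_label[id(v)],
                    "target": edge_label[id(u)],
                }
            )
            subs = [on_edge(v, t_ev), on_edge(u, t_ev)]
            return _join(subs, t_ev)
        tally["sorting"] += 1
        events.append({"type": "loss", "time": t_ev, "host": edge_label[id(v)]})
        return None, t_ev

    # wait-time semantics: leaf subtrees are born at the host-leaf time,
    # internal subtrees at their event time; the caller sets branch lengths.
    root_sub, t_birth = at_node(host.root, 0.0)
    if root_sub is None:
        raise RuntimeError(
            "all parasite lineages went extinct; retry with another seed or "
            "lower r_loss"
        )
    root_sub.length = None
    parasite = PhyloTree(root_sub)
    pairs = [
        (leaf, host_label)
        for leaf, host_label in zip(parasite.leaf_labels(), _leaf_hosts_in_order(parasite, leaf_hosts))
    ]
    links = HostParasiteLinks.from_pairs(pairs)
    return parasite, links, tally, events


def _leaf_hosts_in_order(parasite: PhyloTree, leaf_hosts: list[str]) -> list[str]:
    # parasite leaves were labeled P1..Pk in creation order; leaf_hosts is in
    # the same creation order, so map by the numeric suffix
    by_index = {f"P{i + 1}": h for i, h in enumerate(leaf_hosts)}
    return [by_index[lab] for lab in parasite.leaf_labels()]


# ---------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_sequences(
    tree: PhyloTree,
    length: int,
    rate: float,
    seed=None,
    model: str = "JC",
    gamma_shape: float | None = None,
) -> SeqAlignment:
    """Evolve sequences along a tree under Jukes-Cantor.

    The root sequence is uniform over {A, C, G, T}; along a branch of
    length b each site changes with probability (3/4)(1 - exp(-4 r b / 3))
    to one of the three other bases.  With ``gamma_shape`` set, per-site
    rate multipliers are drawn once from Gamma(alpha, 1/alpha).
    """
    if model != "JC":
        raise ValueError("only the JC model is implemented")
    if rate < 0 or length < 1:
        raise ValueError("need rate >= 0 and length >= 1")
    rng = np.random.default_rng(seed)
    site_rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
        if gamma_shape
        else np.ones(length)
    )
    root_seq = rng.integers(4, size=length)
    seqs: dict[str, np.ndarray] = {}

    def evolve(node: Node, seq: np.ndarray):
        for child in node.children:
            if child.length is None:
                raise ValueError("tree must have branch lengths")
            p_change = 0.75 * (1.0 - np.exp(-4.0 * rate * child.length * site_rates / 3.0))
            mutate = rng.random(length) < p_change
            child_seq = seq.copy()
            if mutate.any():
                # jump to one of the other three bases uniformly
                shift = rng.integers(1, 4, size=int(mutate.sum()))
                child_seq[mutate] = (child_seq[mutate] + shift) % 4
            if child.is_leaf:
                seqs[child.label] = child_seq
            else:
                evolve(child, child_seq)

    if tree.root.is_leaf:
        seqs[tree.root.label] = root_seq
    else:
        evolve(tree.root, root_seq)
    labels = sorted(seqs)
    return SeqAlignment(labels, ["".join(_BASES[seqs[lab]]) for lab in labels])
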