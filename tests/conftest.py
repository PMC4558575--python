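import numpy as np
import pytest

import cophylokit as ck


@pytest.fixture
def three_leaf_pair():
    """Identical 3-leaf host/parasite trees with 1:1 links."""
    host = ck.parse_newick("((A,B),C);")
    parasite = ck.parse_newick("((a,b),c);")
    links = ck.HostParasiteLinks.from_pairs([("a", "A"), ("b", "B"), ("c", "C")])
    return host, parasite, links


def make_congruent_pair(n, seed, lam=1.0):
    """A Yule host tree, its mirrored parasite tree, and 1:1 links."""
    host = ck.simulate_yule(n, lam, seed=seed, prefix="H")
    parasite = host.copy()
    for leaf in parasite.leaves():
        leaf.label = "P" + leaf.label[1:]
    links = ck.HostParasiteLinks.from_pairs(
        [("P" + lab[1:], lab) for lab in host.leaf_labels()]
    )
    return host, parasite, links


def random_tanglegram(rng, n_host_max=5, n_par_max=5):
    """A random small tanglegram (PDA topologies, random leaf links)."""
    n_h = int(rng.integers(2, n_host_max + 1))
    n_p = int(rng.integers(2, n_par_max + 1))
    host = ck.simulate_pda([f"H{i}" for i in range(n_h)], seed=int(rng.integers(2**31)))
    parasite = ck.simulate_pda(
        [f"p{i}" for i in range(n_p)], seed=int(rng.integers(2**31))
    )
    pairs = [
        (lab, f"H{rng.integers(n_h)}") for lab in parasite.leaf_labels()
    ]
    return host, parasite, ck.HostParasiteLinks.from_pairs(pairs)
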