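"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic program: the
reconciliation oracle enumerates every assignment of parasite internal
nodes to host vertices and evaluates the implied events directly, and
the patristic oracle enumerates root paths explicitly.
"""

from __future__ import annotations

import itertools
import math


def _host_tables(host):
    """Vertices, ancestor relation and edge distances of a host tree."""
    nodes = list(host.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = [None] * n
    for i, node in enumerate(nodes):
        for c in node.children:
            parent[idx[id(c)]] = i
    anc = [[False] * n for _ in range(n)]
    for i, node in enumerate(nodes):
        anc[i][i] = True
        for c in node.children:
            k = idx[id(c)]
            for j in range(n):
                anc[i][j] = anc[i][j] or anc[k][j]
    dist = [[None] * n for _ in range(n)]
    for j in range(n):
        d, cur = 0, j
        while cur is not None:
            dist[cur][j] = d
            cur = parent[cur]
            d += 1
    return nodes, idx, parent, anc, dist


def brute_force_min_cost(host, parasite, links, costs, root_to_root=True,
                         charge_dup_with_switch=False):
    """Minimum reconciliation cost by exhaustive assignment enumeration.

    Every parasite internal node is assigned to every host vertex in
    turn; for each full assignment the cheapest valid event
    interpretation of every parasite divergence is summed (infeasible
    assignments score infinity).
    """
    nodes, idx, parent, anc, dist = _host_tables(host)
    n = len(nodes)
    leaf_of = {nodes[i].label: i for i in range(n) if not nodes[i].children}

    pnodes = list(parasite.postorder())
    pidx = {id(p): i for i, p in enumerate(pnodes)}
    internal = [i for i, p in enumerate(pnodes) if p.children]
    fixed = {}
    for i, p in enumerate(pnodes):
        if not p.children:
            hosts = links.hosts_of(p.label)
            assert len(hosts) == 1
            fixed[i] = leaf_of[hosts[0]]

    c_c, c_s, c_d = costs.cosp, costs.sort, costs.dup
    c_w = costs.switch + (costs.dup if charge_dup_with_switch else 0.0)
    proot = pidx[id(parasite.root)]
    hroot = idx[id(host.root)]

    def incomparable(a, b):
        return not anc[a][b] and not anc[b][a]

    best = math.inf
    for combo in itertools.product(range(n), repeat=len(internal)):
        M = dict(fixed)
        M.update(dict(zip(internal, combo)))
        total = 0.0
        if root_to_root:
            total += c_s * dist[hroot][M[proot]]
        ok = True
        for i in internal:
            p = pnodes[i]
            h = M[i]
            h1, h2 = (M[pidx[id(c)]] for c in p.children)
            options = []
            # cospeciation: children in distinct child subtrees of h
            if nodes[h].children:
                holders = []
                for c in nodes[h].children:
                    k = idx[id(c)]
                    holders.append(k)
                ka = next((k for k in holders if anc[k][h1]), None)
                kb = next((k for k in holders if anc[k][h2]), None)
                if ka is not None and kb is not None and ka != kb:
                    options.append(
                        c_c + c_s * (dist[ka][h1] + dist[kb][h2])
                    )
            # duplication: both children inside the subtree of h
            if anc[h][h1] and anc[h][h2]:
                options.append(c_d + c_s * (dist[h][h1] + dist[h][h2]))
            # host-switch: one child stays, the other lands incomparably
            if anc[h][h1] and incomparable(h, h2):
                options.append(c_w + c_s * dist[h][h1])
            if anc[h][h2] and incomparable(h, h1):
                options.append(c_w + c_s * dist[h][h2])
            if not options:
                ok = False
                break
            total += min(options)
        if ok and total < best:
            best = total
    return best


def patristic_by_root_paths(tree):
    """Leaf-pair distances via explicit root-path intersection."""
    paths = {}

    def walk(node, acc):
        if not node.children:
            paths[node.label] = acc
        for c in node.children:
            walk(c, acc + [(id(c), c.length)])

    walk(tree.root, [])
    out = {}
    for a in paths:
        for b in paths:
            pa = dict(paths[a])
            pb = dict(paths[b])
            shared = set(pa) & set(pb)
            out[(a, b)] = sum(pa.values()) + sum(pb.values()) - 2 * sum(
                pa[e] for e in shared
            )
    return out


def chronology_feasible_by_enumeration(host, switches):
    """Check switch timing feasibility over all orders of internal nodes.

    Times for internal host nodes are taken as any permutation ranking
    consistent with the tree's ancestor order; leaves sit at the present
    (after every internal node).  A switch between the edges above
    vertices s and t is feasible when the two edges overlap in time.
    """
    import itertools as it

    nodes = list(host.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    internal = [i for i, n in enumerate(nodes) if n.children]
    parent = {}
    for i, n in enumerate(nodes):
        for c in n.children:
            parent[idx[id(c)]] = i
    name = {}
    for i, n in enumerate(nodes):
        if n.children:
            leaves = []
            stack = [n]
            while stack:
                cur = stack.pop()
                if cur.children:
                    stack.extend(cur.children)
                else:
                    leaves.append(cur.label)
            name[f"<{min(leaves)}|{len(leaves)}>"] = i
        else:
            name[n.label] = i

    present = len(internal)  # any internal rank is before the present

    def rank(order, v):
        return order.index(v) if v in order else present

    for order in it.permutations(internal):
        # respect ancestor order
        if any(
            order.index(parent[i]) > order.index(i)
            for i in internal
            if i in parent
        ):
            continue
        ok = True
        for s_name, t_name in switches:
            s, t = name[s_name], name[t_name]
            # edge above v spans (rank(parent[v]), rank(v)); leaves end at present
            s0, s1 = rank(order, parent[s]), rank(order, s)
            t0, t1 = rank(order, parent[t]), rank(order, t)
            if not (s0 < t1 and t0 < s1):
                ok = False
                break
        if ok:
            return True
    return False
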