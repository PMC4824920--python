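"""Independent oracles used by the test suite.

Everything here recomputes quantities by a different route than the package:
breadth-first path sums for patristic distances, dense grid + local
refinement for Procrustes, exhaustive enumeration over event mappings for
reconciliation, and exact forward recursion for simulator expectations.
"""
from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.optimize import minimize_scalar

from cophylo.reconcile import CostRegime
from cophylo.trees import PhyloTree

INF = float("inf")


# ---------------------------------------------------------------- patristic


def bfs_patristic(tree: PhyloTree) -> dict:
    """Patristic distances by breadth-first search on the node graph."""
    adj: dict = {}
    for node in tree.preorder():
        for child in node.children:
            adj.setdefault(id(node), []).append((id(child), child.length))
            adj.setdefault(id(child), []).append((id(node), child.length))
    leaves = {id(n): n.label for n in tree.leaves()}
    out = {}
    for start, lab in leaves.items():
        dist = {start: 0.0}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            for nxt, w in adj.get(cur, []):
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    queue.append(nxt)
        for other, olab in leaves.items():
            out[(lab, olab)] = dist[other]
    return out


# ---------------------------------------------------------------- procrustes


def grid_procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum residual sum of squares of s*y@R + t onto x over translation,
    planar rotation (with reflection), and scale, by angle grid + refinement.

    Only valid for 2-column configurations.  For a fixed rotation the optimal
    translation and scale follow from ordinary least squares, derived here
    directly rather than via the SVD route the package uses.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    assert x.shape[1] == 2 and y.shape[1] == 2
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    ynorm2 = (yc**2).sum()

    def m2_at(theta: float, reflect: bool) -> float:
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        if reflect:
            rot = rot @ np.diag([1.0, -1.0])
        yr = yc @ rot
        scale = max((yr * xc).sum() / ynorm2, 0.0)
        return float(((xc - scale * yr) ** 2).sum())

    best = INF
    for reflect in (False, True):
        coarse = min(
            np.linspace(0.0, 2 * np.pi, 3600, endpoint=False),
            key=lambda th: m2_at(th, reflect),
        )
        res = minimize_scalar(
            lambda th: m2_at(th, reflect),
            bounds=(coarse - 0.01, coarse + 0.01),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


# ------------------------------------------------------------ reconciliation


def _host_structures(host: PhyloTree):
    nodes = list(host.postorder())
    parent = {}
    for n in host.preorder():
        for c in n.children:
            parent[id(c)] = n
    depth = {}
    for n in host.preorder():
        depth[id(n)] = depth[id(parent[id(n)])] + 1 if id(n) in parent else 0
    anc: dict = {id(n): set() for n in nodes}  # ancestors-or-self of each node

    for n in nodes:
        cur = n
        while True:
            anc[id(n)].add(id(cur))
            if id(cur) not in parent:
                break
            cur = parent[id(cur)]
    leaf_of = {n.label: n for n in nodes if not n.children}
    return nodes, parent, depth, anc, leaf_of


def brute_min_cost(
    host: PhyloTree,
    symb: PhyloTree,
    links,
    regime: CostRegime = CostRegime(),
    zone_of_label: dict | None = None,
    min_zone: int = 1,
):
    """Exhaustive minimum over all mappings of internal symbiont nodes to
    host nodes, classifying the cheapest valid event at each node.

    Returns (min cost, counts at one optimum) or (inf, None) when no valid
    mapping exists.  Intended for trees with at most ~6 leaves each.
    """
    hnodes, parent, depth, anc, leaf_of = _host_structures(host)
    leaf_map = links.symbiont_to_host()
    zone = None
    if zone_of_label is not None:
        zone = {id(n): zone_of_label[n.label] for n in hnodes}

    snodes = list(symb.postorder())
    internals = [n for n in snodes if n.children]
    pos: dict = {}
    for n in snodes:
        if not n.children:
            pos[id(n)] = leaf_of[leaf_map[n.label]]

    def node_cost(snode, e):
        """Cheapest valid event for snode placed at host node e, or inf."""
        if zone is not None and zone[id(e)] < min_zone:
            return INF, None
        c1, c2 = snode.children
        h1, h2 = pos[id(c1)], pos[id(c2)]
        best, best_counts = INF, None
        if e.children:
            for a, b in ((e.children[0], e.children[1]), (e.children[1], e.children[0])):
                if id(a) in anc[id(h1)] and id(b) in anc[id(h2)]:
                    lost = (depth[id(h1)] - depth[id(a)]) + (depth[id(h2)] - depth[id(b)])
                    cost = regime.cospeciation + regime.loss * lost
                    if cost < best:
                        best, best_counts = cost, (1, 0, 0, lost)
        if id(e) in anc[id(h1)] and id(e) in anc[id(h2)]:
            lost = (depth[id(h1)] - depth[id(e)]) + (depth[id(h2)] - depth[id(e)])
            cost = regime.duplication + regime.loss * lost
            if cost < best:
                best, best_counts = cost, (0, 1, 0, lost)
        for stay, move in ((h1, h2), (h2, h1)):
            if id(e) not in anc[id(stay)]:
                continue
            t_best = None
            for t in hnodes:
                if id(t) in anc[id(move)] and id(t) not in anc[id(e)]:
                    if zone is not None and zone[id(t)] != zone[id(e)]:
                        continue
                    if t_best is None or depth[id(t)] > depth[id(t_best)]:
                        t_best = t
            if t_best is None:
                continue
            lost = (depth[id(stay)] - depth[id(e)]) + (
                depth[id(move)] - depth[id(t_best)]
            )
            cost = regime.switch + regime.loss * lost
            if cost < best:
                best, best_counts = cost, (0, 0, 1, lost)
        return best, best_counts

    best_total = [INF]
    best_counts = [None]

    def recurse(k: int, partial: float, counts):
        if partial >= best_total[0]:
            return
        if k == len(internals):
            best_total[0] = partial
            best_counts[0] = counts
            return
        snode = internals[k]  # postorder: children already placed
        for e in hnodes:
            pos[id(snode)] = e
            cost, c = node_cost(snode, e)
            if np.isfinite(cost):
                recurse(
                    k + 1,
                    partial + cost,
                    tuple(a + b for a, b in zip(counts, c)),
                )
        pos.pop(id(snode), None)

    recurse(0, 0.0, (0, 0, 0, 0))
    return best_total[0], best_counts[0]


def random_instance(rng: np.random.Generator, max_leaves: int = 6):
    """A random reconciliation instance (host, symbiont, links)."""
    from cophylo.associations import AssociationMap
    from cophylo.simulate import simulate_host_tree

    nh = int(rng.integers(3, max_leaves + 1))
    ns = int(rng.integers(3, max_leaves + 1))
    host = simulate_host_tree(nh, seed=int(rng.integers(2**31)))
    symb = simulate_host_tree(ns, seed=int(rng.integers(2**31)))
    # relabel symbiont leaves to avoid clashing with host labels
    for leaf in symb.leaves():
        leaf.label = leaf.label.replace("H", "s")
    hosts = host.leaf_labels
    links = AssociationMap(
        [(hosts[int(rng.integers(nh))], s) for s in symb.leaf_labels]
    )
    return host, symb, links


# ------------------------------------------------------------- simulation


def expected_losses_no_duplication(host: PhyloTree, p_loss: float) -> float:
    """Exact expected loss count when lineages never duplicate.

    At a host speciation each lineage present either cospeciates (one
    daughter onto each child edge) or is lost onto one uniformly chosen
    child.  By linearity, E[losses] = sum over internal host nodes v of
    E[#lineages at v] * p_loss, and the expected lineage count entering a
    child edge is E[#at v] * (p_cosp + p_loss/2).
    """
    p_follow = (1.0 - p_loss) + p_loss * 0.5
    total = [0.0]

    def walk(node, p_reach):
        if not node.children:
            return
        total[0] += p_reach * p_loss
        for child in node.children:
            walk(child, p_reach * p_follow)

    walk(host.root, 1.0)
    return total[0]
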