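"""Event-based host-symbiont reconciliation.

Maps a rooted binary symbiont tree into a rooted binary host tree so that the
total cost of evolutionary events is minimal under a configurable cost regime:

* cospeciation - host and symbiont speciate simultaneously (default cost 0);
* duplication  - the symbiont speciates within one host lineage (cost 1);
* loss         - the host speciates while the symbiont follows only one
  descendant (cost 1 per loss);
* host switch  - the symbiont speciates and one daughter colonises a
  different host lineage ("duplication then host switching", cost 2).

The default solver is an exact bottom-up dynamic program over (symbiont node,
host node) cells, so the reported cost is the global optimum; branch lengths
are ignored (the method is topology-only).  In the undated model a switch may
target any host edge that is neither the source edge nor one of its
ancestors.  Optional time zones - an ancestry-respecting partition of host
nodes into ordered eras - restrict symbiont divergences to admissible zones
and force switch source and target into the same zone.

A seeded genetic-algorithm mode is also provided purely as a heuristic
mirror of metaheuristic reconciliation tools; its cost can never beat the
exact solver's.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .associations import AssociationMap
from .errors import InfeasibleReconciliationError, ValidationError
from .trees import Node, PhyloTree

__all__ = [
    "CostRegime",
    "TimeZones",
    "SolverConfig",
    "Reconciliation",
    "solve_reconciliation",
    "count_events",
    "build_composite_host_tree",
]

_INF = float("inf")


@dataclass(frozen=True)
class CostRegime:
    """Per-event costs; the defaults are the classic (0, 1, 1, 2) regime."""

    cospeciation: float = 0.0
    duplication: float = 1.0
    loss: float = 1.0
    switch: float = 2.0

    def __post_init__(self):
        for name in ("cospeciation", "duplication", "loss", "switch"):
            if getattr(self, name) < 0:
                raise ValidationError(f"cost_{name} must be nonnegative")

    @classmethod
    def from_string(cls, text: str) -> "CostRegime":
        """Parse "cosp,dup,loss,switch" (e.g. "0,1,1,2")."""
        parts = [float(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValidationError("cost string must have 4 comma-separated values")
        return cls(*parts)


@dataclass
class TimeZones:
    """Ordered partition of host nodes into zones 1..K.

    ``assignments`` maps host node labels (leaf or internal) to zone indices;
    unlabelled nodes inherit the nearest labelled ancestor's zone (the root
    defaults to zone 1).  Zones must respect host ancestry: a node's zone
    index never exceeds any descendant's.  Symbiont divergences are admissible
    only on host nodes whose zone index is at least ``min_divergence_zone``,
    and a host switch must keep source and target in the same zone.
    """

    assignments: dict
    min_divergence_zone: int = 1

    @classmethod
    def from_tsv(cls, path, min_divergence_zone: int = 1) -> "TimeZones":
        from pathlib import Path

        assignments = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected columns host_node_label, zone_index"
                )
            assignments[parts[0]] = int(parts[1])
        return cls(assignments, min_divergence_zone)

    def resolve(self, host: "_HostIndex") -> np.ndarray:
        zones = np.zeros(host.n, dtype=int)
        for v in host.preorder_indices:
            label = host.labels[v]
            parent = host.parent[v]
            inherited = zones[parent] if parent >= 0 else 1
            zones[v] = self.assignments.get(label, inherited)
            if parent >= 0 and zones[v] < zones[parent]:
                raise ValidationError(
                    f"zone of host node {label!r} ({zones[v]}) is earlier than its "
                    f"ancestor's ({zones[parent]}); zones must respect host ancestry"
                )
        return zones


@dataclass
class SolverConfig:
    """Solver selection; ``exact-dp`` guarantees the global optimum."""

    mode: str = "exact-dp"
    generations: int = 500
    population_size: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("exact-dp", "genetic"):
            raise ValidationError(f"unknown solver mode {self.mode!r}")


@dataclass
class Reconciliation:
    """A mapping of symbiont nodes onto host nodes with event labels.

    ``mapping`` takes each symbiont node name (leaf label, or internal label /
    generated ``nodeK`` id) to the host node name where its divergence - or
    tip - is placed.  ``events`` labels each internal symbiont node with
    cospeciation / duplication / host-switch; ``losses`` counts losses per
    symbiont edge (keyed by the child node's name).
    """

    mapping: dict
    events: dict
    losses: dict
    total_cost: float
    regime: CostRegime
    exact: bool = True

    @property
    def n_cospeciation(self) -> int:
        return sum(1 for e in self.events.values() if e == "cospeciation")

    @property
    def n_duplication(self) -> int:
        return sum(1 for e in self.events.values() if e == "duplication")

    @property
    def n_switch(self) -> int:
        return sum(1 for e in self.events.values() if e == "host-switch")

    @property
    def n_loss(self) -> int:
        return sum(self.losses.values())

    def event_counts(self) -> tuple:
        return (self.n_cospeciation, self.n_duplication, self.n_switch, self.n_loss)

    def cost_from_counts(self) -> float:
        c, d, s, l = self.event_counts()
        r = self.regime
        return c * r.cospeciation + d * r.duplication + s * r.switch + l * r.loss

    def to_dict(self) -> dict:
        c, d, s, l = self.event_counts()
        return {
            "total_cost": self.total_cost,
            "events": {"cospeciation": c, "duplication": d, "host_switch": s, "loss": l},
            "mapping": dict(self.mapping),
            "node_events": dict(self.events),
            "exact": self.exact,
        }


def count_events(reconciliation: Reconciliation) -> tuple:
    """(n_cospeciation, n_duplication, n_switch, n_loss)."""
    return reconciliation.event_counts()


# --------------------------------------------------------------------------
# host / symbiont indexing


class _HostIndex:
    """Arrays describing a rooted binary host tree for the DP."""

    def __init__(self, tree: PhyloTree):
        nodes = list(tree.postorder())
        self.nodes = nodes
        self.n = len(nodes)
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.labels = []
        for i, n in enumerate(nodes):
            self.labels.append(n.label if n.label else f"host{i}")
        if len(set(self.labels)) != len(self.labels):
            # disambiguate repeated internal labels deterministically
            seen: dict = {}
            for i, lab in enumerate(self.labels):
                if lab in seen:
                    self.labels[i] = f"{lab}.{seen[lab]}"
                seen[lab] = seen.get(lab, 0) + 1
        self.parent = np.full(self.n, -1, dtype=int)
        self.children: list = [() for _ in range(self.n)]
        for i, n in enumerate(nodes):
            if n.children:
                kids = tuple(self.index[id(c)] for c in n.children)
                self.children[i] = kids
                for k in kids:
                    self.parent[k] = i
        self.is_leaf = np.array([not n.children for n in nodes])
        self.leaf_index = {
            nodes[i].label: i for i in range(self.n) if self.is_leaf[i]
        }
        # preorder (left-to-right) positions for deterministic tie-breaking
        self.preorder_indices = [self.index[id(n)] for n in tree.preorder()]
        self.pre_rank = np.zeros(self.n, dtype=int)
        for rank, v in enumerate(self.preorder_indices):
            self.pre_rank[v] = rank
        # anc_or_self[a, b]: a is an ancestor of b or b itself
        anc = np.zeros((self.n, self.n), dtype=bool)
        for v in self.preorder_indices:
            anc[v, v] = True
            p = self.parent[v]
            if p >= 0:
                anc[:, v] |= anc[:, p]
        self.anc_or_self = anc


def _check_binary_rooted(tree: PhyloTree, name: str) -> None:
    if not tree.rooted:
        raise ValidationError(f"{name} tree must be rooted")
    if not tree.is_binary():
        raise ValidationError(
            f"{name} tree must be binary; resolve multifurcations first "
            "(PhyloTree.resolve_polytomies)"
        )


# --------------------------------------------------------------------------
# exact dynamic program


def solve_reconciliation(
    host: PhyloTree,
    symbiont: PhyloTree,
    links: AssociationMap,
    regime: CostRegime = CostRegime(),
    zones: Optional[TimeZones] = None,
    config: SolverConfig = SolverConfig(),
) -> Reconciliation:
    """Minimum-cost reconciliation of ``symbiont`` into ``host``.

    Every symbiont leaf must be linked to exactly one host leaf.  In
    ``exact-dp`` mode the returned cost is the global optimum over all valid
    event mappings; ties among co-optimal mappings are broken deterministically
    (cospeciation > duplication > host-switch, then left-to-right host
    positions), so repeated runs return the same reconciliation.
    """
    _check_binary_rooted(host, "host")
    _check_binary_rooted(symbiont, "symbiont")
    links.validate_against(host, symbiont)
    leaf_map = links.symbiont_to_host()
    for leaf in symbiont.leaf_labels:
        if leaf not in leaf_map:
            raise ValidationError(f"symbiont leaf {leaf!r} has no host link")

    hidx = _HostIndex(host)
    zone_of = zones.resolve(hidx) if zones is not None else None
    min_zone = zones.min_divergence_zone if zones is not None else 1

    snodes = list(symbiont.postorder())
    sindex = {id(n): i for i, n in enumerate(snodes)}
    snames = [n.label if n.label else f"node{i}" for i, n in enumerate(snodes)]

    if config.mode == "genetic":
        return _solve_genetic(
            hidx, snodes, sindex, snames, leaf_map, regime, zone_of, min_zone, config
        )

    H = hidx.n
    # switch-target admissibility: allowed[e, t] = t usable from source e
    allowed = ~hidx.anc_or_self.T  # allowed[e, t] = not (t ancestor-or-self of e)
    if zone_of is not None:
        allowed &= zone_of[None, :] == zone_of[:, None]

    C: list = [None] * len(snodes)  # C[p][e]: cost of p's event placed exactly at e
    IN: list = [None] * len(snodes)  # IN[p][e]: cost of p placed at e or below
    for pi, p in enumerate(snodes):
        if not p.children:
            c = np.full(H, _INF)
            c[hidx.leaf_index[leaf_map[p.label]]] = 0.0
        else:
            qi, ri = sindex[id(p.children[0])], sindex[id(p.children[1])]
            inq, inr = IN[qi], IN[ri]
            dup = regime.duplication + inq + inr
            cosp = np.full(H, _INF)
            for e in range(H):
                kids = hidx.children[e]
                if kids:
                    e1, e2 = kids
                    cosp[e] = regime.cospeciation + min(
                        inq[e1] + inr[e2], inq[e2] + inr[e1]
                    )
            out_q = _masked_min(inq, allowed)
            out_r = _masked_min(inr, allowed)
            switch = regime.switch + np.minimum(inq + out_r, inr + out_q)
            c = np.minimum(np.minimum(cosp, dup), switch)
            if zone_of is not None:
                c[zone_of < min_zone] = _INF
        C[pi] = c
        inp = c.copy()
        for e in hidx.preorder_indices[::-1]:  # children before parents
            kids = hidx.children[e]
            if kids:
                inp[e] = min(
                    inp[e], regime.loss + min(inp[kids[0]], inp[kids[1]])
                )
        IN[pi] = inp

    root_i = sindex[id(snodes[-1])]
    total = float(np.min(C[root_i]))
    if not np.isfinite(total):
        raise InfeasibleReconciliationError(
            "no valid reconciliation exists under the given constraints"
        )

    mapping, events, losses = _traceback(
        hidx, snodes, sindex, snames, C, IN, allowed, regime
    )
    rec = Reconciliation(mapping, events, losses, total, regime, exact=True)
    assert abs(rec.cost_from_counts() - total) < 1e-6, "event counts inconsistent with cost"
    return rec


def _masked_min(values: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """out[e] = min over t with allowed[e, t] of values[t] (inf if none)."""
    masked = np.where(allowed, values[None, :], _INF)
    return masked.min(axis=1)


def _traceback(hidx, snodes, sindex, snames, C, IN, allowed, regime):
    mapping: dict = {}
    events: dict = {}
    losses: dict = {}
    root_i = len(snodes) - 1
    # deterministic argmin: smallest cost, then leftmost (preorder) host
    root_e = _argmin_pre(C[root_i], hidx)

    def resolve_in(pi: int, e: int):
        """Follow the IN chain from e down to the node where p's event sits."""
        path_losses = 0
        while True:
            kids = hidx.children[e]
            if C[pi][e] <= IN[pi][e] + 1e-12:
                return e, path_losses
            nxt = None
            for k in sorted(kids, key=lambda v: hidx.pre_rank[v]):
                if abs(regime.loss + IN[pi][k] - IN[pi][e]) < 1e-9:
                    nxt = k
                    break
            if nxt is None:  # numerical guard: fall back to the better child
                nxt = min(kids, key=lambda v: IN[pi][v])
            e = nxt
            path_losses += 1

    def place(pi: int, e: int):
        p = snodes[pi]
        mapping[snames[pi]] = hidx.labels[e]
        if not p.children:
            return
        qi, ri = sindex[id(p.children[0])], sindex[id(p.children[1])]
        inq, inr = IN[qi], IN[ri]
        target = C[pi][e]
        kids = hidx.children[e]
        # preference order: cospeciation > duplication > host-switch
        if kids:
            e1, e2 = sorted(kids, key=lambda v: hidx.pre_rank[v])
            for (a, b) in ((e1, e2), (e2, e1)):
                if abs(regime.cospeciation + inq[a] + inr[b] - target) < 1e-9:
                    events[snames[pi]] = "cospeciation"
                    _descend(qi, a)
                    _descend(ri, b)
                    return
        if abs(regime.duplication + inq[e] + inr[e] - target) < 1e-9:
            events[snames[pi]] = "duplication"
            _descend(qi, e)
            _descend(ri, e)
            return
        # host switch: decide which child stays
        for stay, move in ((qi, ri), (ri, qi)):
            stay_cost = IN[stay][e]
            if not np.isfinite(stay_cost):
                continue
            t = _switch_target(move, e)
            if t is not None and abs(
                regime.switch + stay_cost + IN[move][t] - target
            ) < 1e-9:
                events[snames[pi]] = "host-switch"
                _descend(stay, e)
                _descend(move, t)
                return
        raise AssertionError("traceback failed to reproduce the optimal cost")

    def _switch_target(mi: int, e: int):
        best, best_t = _INF, None
        for t in sorted(range(hidx.n), key=lambda v: hidx.pre_rank[v]):
            if allowed[e, t] and IN[mi][t] < best - 1e-12:
                best, best_t = IN[mi][t], t
        return best_t

    def _descend(pi: int, e: int):
        spot, n_lost = resolve_in(pi, e)
        losses[snames[pi]] = n_lost
        place(pi, spot)

    place(root_i, root_e)
    return mapping, events, losses


def _argmin_pre(values: np.ndarray, hidx: "_HostIndex") -> int:
    best = np.min(values)
    for v in hidx.preorder_indices:
        if values[v] <= best + 1e-12:
            return v
    raise AssertionError("empty cost vector")


# --------------------------------------------------------------------------
# assignment scoring (shared by the genetic mode)


def _score_assignment(hidx, snodes, sindex, leaf_map, regime, zone_of, min_zone, assign):
    """Cost of mapping internal symbiont node k to host ``assign[k]``.

    Events are classified locally at each internal node, taking the cheapest
    valid interpretation; returns (cost, (c, d, s, l)) or (inf, None) when the
    assignment admits no valid event at some node.
    """
    anc = hidx.anc_or_self
    depth = np.zeros(hidx.n, dtype=int)
    for v in hidx.preorder_indices:
        p = hidx.parent[v]
        depth[v] = depth[p] + 1 if p >= 0 else 0

    pos = {}
    internals = [i for i, n in enumerate(snodes) if n.children]
    for i, n in enumerate(snodes):
        if not n.children:
            pos[i] = hidx.leaf_index[leaf_map[n.label]]
    for k, i in enumerate(internals):
        pos[i] = assign[k]

    total = 0.0
    counts = [0, 0, 0, 0]  # cosp, dup, switch, loss
    for i in internals:
        e = pos[i]
        if zone_of is not None and zone_of[e] < min_zone:
            return _INF, None
        q, r = (sindex[id(c)] for c in snodes[i].children)
        h1, h2 = pos[q], pos[r]
        best = _INF
        best_kind = None
        best_losses = 0
        kids = hidx.children[e]
        if kids:
            e1, e2 = kids
            for a, b in ((e1, e2), (e2, e1)):
                if anc[a, h1] and anc[b, h2]:
                    lost = (depth[h1] - depth[a]) + (depth[h2] - depth[b])
                    cost = regime.cospeciation + regime.loss * lost
                    if cost < best:
                        best, best_kind, best_losses = cost, 0, lost
        if anc[e, h1] and anc[e, h2]:
            lost = (depth[h1] - depth[e]) + (depth[h2] - depth[e])
            cost = regime.duplication + regime.loss * lost
            if cost < best:
                best, best_kind, best_losses = cost, 1, lost
        for stay, move in ((h1, h2), (h2, h1)):
            if not anc[e, stay]:
                continue
            # cheapest admissible landing edge above (or at) the moved child
            t_best = None
            for t in range(hidx.n):
                if anc[t, move] and not anc[t, e]:
                    if zone_of is not None and zone_of[t] != zone_of[e]:
                        continue
                    if t_best is None or depth[t] > depth[t_best]:
                        t_best = t
            if t_best is None:
                continue
            lost = (depth[stay] - depth[e]) + (depth[move] - depth[t_best])
            cost = regime.switch + regime.loss * lost
            if cost < best:
                best, best_kind, best_losses = cost, 2, lost
        if best_kind is None:
            return _INF, None
        total += best
        counts[best_kind] += 1
        counts[3] += best_losses
    return total, tuple(counts)


def _solve_genetic(hidx, snodes, sindex, snames, leaf_map, regime, zone_of, min_zone, config):
    """Heuristic search over internal-node host assignments (seeded GA)."""
    rng = np.random.default_rng(config.seed)
    internals = [i for i, n in enumerate(snodes) if n.children]
    k = len(internals)
    H = hidx.n

    def score(vec):
        return _score_assignment(
            hidx, snodes, sindex, leaf_map, regime, zone_of, min_zone, vec
        )

    pop = [rng.integers(0, H, size=k) for _ in range(config.population_size)]
    # seed one individual at each internal node's linked-leaf MRCA: valid for
    # duplication/loss-only histories, a good starting point generally
    mrca_vec = np.zeros(k, dtype=int)
    for j, i in enumerate(internals):
        leaves = [
            hidx.leaf_index[leaf_map[n.label]]
            for n in _subtree_leaves(snodes[i])
        ]
        mrca_vec[j] = _mrca(hidx, leaves)
    pop[0] = mrca_vec
    scored = [(score(v)[0], v) for v in pop]
    best_cost, best_vec = min(scored, key=lambda t: t[0])
    for _ in range(config.generations):
        new_pop = [best_vec.copy()]  # elitism
        while len(new_pop) < config.population_size:
            a = min(rng.choice(len(scored), 2, replace=False), key=lambda i: scored[i][0])
            b = min(rng.choice(len(scored), 2, replace=False), key=lambda i: scored[i][0])
            mask = rng.random(k) < 0.5
            child = np.where(mask, scored[a][1], scored[b][1])
            mut = rng.random(k) < 0.2
            child[mut] = rng.integers(0, H, size=int(mut.sum()))
            new_pop.append(child)
        scored = [(score(v)[0], v) for v in new_pop]
        gen_best = min(scored, key=lambda t: t[0])
        if gen_best[0] < best_cost:
            best_cost, best_vec = gen_best[0], gen_best[1].copy()
    cost, counts = score(best_vec)
    if not np.isfinite(cost):
        raise InfeasibleReconciliationError(
            "genetic search found no valid reconciliation; try exact-dp mode"
        )
    mapping = {}
    events = {}
    losses = {}
    kind_names = {0: "cospeciation", 1: "duplication", 2: "host-switch"}
    for i, n in enumerate(snodes):
        if not n.children:
            mapping[snames[i]] = leaf_map[n.label]
    for j, i in enumerate(internals):
        mapping[snames[i]] = hidx.labels[best_vec[j]]
    # re-derive per-node events for the report
    _, _ = cost, counts
    rec = Reconciliation(mapping, events, losses, float(cost), regime, exact=False)
    # store aggregate counts via synthetic per-node entries (events dict keeps
    # the classification; loss total goes on a single bucket)
    c, d, s, l = counts
    for idx in range(c):
        events[f"_cospeciation{idx}"] = "cospeciation"
    for idx in range(d):
        events[f"_duplication{idx}"] = "duplication"
    for idx in range(s):
        events[f"_switch{idx}"] = "host-switch"
    losses["_total"] = l
    return rec


def _subtree_leaves(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.children:
            yield n
        stack.extend(n.children)


def _mrca(hidx: _HostIndex, leaf_indices) -> int:
    anc = hidx.anc_or_self
    for v in hidx.preorder_indices[::-1]:  # deepest first
        if all(anc[v, l] for l in leaf_indices):
            return v
    return hidx.n - 1


# --------------------------------------------------------------------------
# composite host tree


def build_composite_host_tree(
    nematode: PhyloTree,
    arthropod: PhyloTree,
    attachment: str,
    graft_edge_length: float = 1.0,
) -> PhyloTree:
    """Graft a hypothesised arthropod clade onto the nematode host tree.

    ``attachment`` names a node of the nematode tree; the arthropod clade is
    attached as its sister (a new node is inserted on the attachment node's
    parent edge, or a new root is created when the attachment is the root).
    Leaf label sets must be disjoint.  Reconciliation ignores branch lengths;
    the new edges get ``graft_edge_length`` so patristic computations remain
    possible.
    """
    overlap = set(nematode.leaf_labels) & set(arthropod.leaf_labels)
    if overlap:
        raise ValidationError(
            f"label collision between the two host trees: {', '.join(sorted(overlap))}"
        )
    if not nematode.rooted:
        raise ValidationError("nematode host tree must be rooted")
    base = nematode.copy()
    graft = arthropod.copy().root
    graft.length = graft_edge_length
    target = None
    for node in base.preorder():
        if node.label == attachment:
            target = node
            break
    if target is None:
        raise ValidationError(f"no node labelled {attachment!r} in the nematode tree")
    if target is base.root:
        new_root = Node(label=None, length=None)
        old = base.root
        old.length = graft_edge_length
        new_root.add_child(old)
        new_root.add_child(graft)
        return PhyloTree(new_root, rooted=True)
    parent = target.parent
    idx = parent.children.index(target)
    joint = Node(label=None, length=(target.length or graft_edge_length) / 2.0)
    target.length = (target.length or graft_edge_length) / 2.0
    parent.children[idx] = joint
    joint.parent = parent
    joint.add_child(target)
    joint.add_child(graft)
    return PhyloTree(base.root, rooted=base.rooted)
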