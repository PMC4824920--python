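"""Forward simulation of host-symbiont coevolution (tanglegrams with truth).

The generator produces a host phylogeny and then evolves symbiont lineages
tipward along it under the four-event vocabulary of event-based
reconciliation:

* at every host speciation a symbiont lineage either **cospeciates**
  (probability ``p_cospeciation``) or misses the speciation and follows one
  randomly chosen host daughter, a **loss** (``p_loss``); the two outcomes
  partition the unit interval, so ``p_cospeciation + p_loss`` must equal 1;
* along each host edge a lineage undergoes at most one **duplication**
  (Bernoulli ``p_duplication``); a duplicated daughter **switches** to a
  uniformly chosen contemporaneous host edge with probability ``p_switch``
  (switches happen only at duplications - "duplication then host switching");
  when no other edge crosses the duplication time the daughter stays put and
  the event is recorded as a plain duplication.

Extinct host lineages are not simulated: reconciliation methods only see
extant tips.  Every realised event is logged, so the recorded event counts
can be checked by replaying the log, and the true symbiont root placement is
reported for root-scan benchmarks.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .associations import AssociationMap
from .errors import ValidationError
from .trees import Node, PhyloTree

__all__ = [
    "SimulationParams",
    "SimulatedCophylogeny",
    "simulate_host_tree",
    "simulate_cophylogeny",
    "replay_event_log",
]


@dataclass(frozen=True)
class SimulationParams:
    """Event probabilities and branch-length model for the simulator.

    ``branch_rate`` is the rate of the exponential edge-length distribution
    of the host tree (lengths in arbitrary time units).
    """

    p_cospeciation: float = 0.85
    p_loss: float = 0.15
    p_duplication: float = 0.10
    p_switch: float = 0.30
    seed: int = 0

    def __post_init__(self):
        for name in ("p_cospeciation", "p_loss", "p_duplication", "p_switch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        total = self.p_cospeciation + self.p_loss
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                "p_cospeciation + p_loss must sum to 1 (they partition the outcome "
                f"at a host speciation); got {total}"
            )


@dataclass
class SimulatedCophylogeny:
    host: PhyloTree
    symbiont: PhyloTree
    links: AssociationMap
    event_counts: dict  # cospeciation / duplication / switch / loss
    true_root_bipartition: Optional[frozenset]  # symbiont leaves under one root child
    event_log: list
    params: SimulationParams

    def true_history_cost(self, regime=None) -> float:
        """Total cost of the generating history under an event-cost regime."""
        from .reconcile import CostRegime

        r = regime or CostRegime()
        c = self.event_counts
        return (
            c["cospeciation"] * r.cospeciation
            + c["duplication"] * r.duplication
            + c["switch"] * r.switch
            + c["loss"] * r.loss
        )

    def to_files(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "host": out / "host.nwk",
            "symbiont": out / "symbiont.nwk",
            "links": out / "links.tsv",
            "truth": out / "truth.json",
        }
        self.host.write(paths["host"])
        self.symbiont.write(paths["symbiont"])
        self.links.to_tsv(paths["links"])
        truth = {
            "event_counts": self.event_counts,
            "true_root_bipartition": sorted(self.true_root_bipartition)
            if self.true_root_bipartition
            else None,
            "params": {
                "p_cospeciation": self.params.p_cospeciation,
                "p_loss": self.params.p_loss,
                "p_duplication": self.params.p_duplication,
                "p_switch": self.params.p_switch,
                "seed": self.params.seed,
            },
        }
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        return paths


def simulate_host_tree(n: int, seed: int = 0, rate: float = 1.0) -> PhyloTree:
    """Random rooted binary host tree with ``n`` leaves.

    Topology grows by uniformly random tip splitting (a Yule-type shape) and
    edge lengths are exponential with the given rate.  Leaves are labelled
    H1..Hn left to right and internal nodes N1.. in preorder, so the tree is
    usable with label-addressed time zones.  Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValidationError("a host tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = Node()
    tips = [root]
    while len(tips) < n:
        tip = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = Node(length=float(rng.exponential(1.0 / rate)))
            tip.add_child(child)
            tips.append(child)
    leaf_counter = internal_counter = 0
    stack = [root]
    while stack:  # preorder labelling, left to right
        node = stack.pop()
        if node.is_leaf:
            leaf_counter += 1
            node.label = f"H{leaf_counter}"
        else:
            internal_counter += 1
            node.label = f"N{internal_counter}"
        stack.extend(reversed(node.children))
    return PhyloTree(root, rooted=True)


def simulate_cophylogeny(
    host: PhyloTree, params: SimulationParams = SimulationParams()
) -> SimulatedCophylogeny:
    """Evolve a symbiont tree tipward along ``host`` (see module docstring)."""
    if not host.rooted or not host.is_binary():
        raise ValidationError("the host tree must be rooted and binary")
    for node in host.preorder():
        if node is not host.root and node.length is None:
            raise ValidationError("host branch lengths are required (they define time)")

    rng = np.random.default_rng(params.seed)
    time_of = {id(host.root): 0.0}
    for node in host.preorder():
        for child in node.children:
            time_of[id(child)] = time_of[id(node)] + child.length
    host_nodes = list(host.preorder())

    def contemporaneous(t: float, exclude: Node) -> list:
        out = []
        for node in host_nodes:
            if node is host.root or node is exclude:
                continue
            t0 = time_of[id(node.parent)]
            t1 = time_of[id(node)]
            if t0 < t <= t1:
                out.append(node)
        return out

    counts = {"cospeciation": 0, "duplication": 0, "switch": 0, "loss": 0}
    log: list = []
    leaf_serial = [0]
    lineage_serial = [0]

    def new_lineage() -> int:
        lineage_serial[0] += 1
        return lineage_serial[0]

    def evolve(lineage: int, host_node: Node, t_entry: float, may_duplicate: bool) -> Node:
        """Lineage travelling the edge that leads to ``host_node``."""
        t_end = time_of[id(host_node)]
        if (
            may_duplicate
            and host_node is not host.root
            and t_entry < t_end
            and rng.random() < params.p_duplication
        ):
            t_dup = float(rng.uniform(t_entry, t_end))
            left_id, right_id = new_lineage(), new_lineage()
            targets = contemporaneous(t_dup, host_node)
            if params.p_switch > 0 and targets and rng.random() < params.p_switch:
                target = targets[int(rng.integers(len(targets)))]
                counts["switch"] += 1
                log.append(
                    {
                        "type": "switch",
                        "lineage": lineage,
                        "host": host_node.label,
                        "target": target.label,
                        "time": t_dup,
                        "daughters": [left_id, right_id],
                    }
                )
                node = Node(length=None)
                node_time = t_dup
                left = evolve(left_id, host_node, t_dup, False)
                right = evolve(right_id, target, t_dup, False)
            else:
                counts["duplication"] += 1
                log.append(
                    {
                        "type": "duplication",
                        "lineage": lineage,
                        "host": host_node.label,
                        "time": t_dup,
                        "daughters": [left_id, right_id],
                    }
                )
                node = Node(length=None)
                node_time = t_dup
                left = evolve(left_id, host_node, t_dup, False)
                right = evolve(right_id, host_node, t_dup, False)
            node.add_child(left)
            node.add_child(right)
            node.label = None
            node.length = node_time  # temporarily store own time; fixed below
            return node
        if host_node.is_leaf:
            leaf_serial[0] += 1
            label = f"s{leaf_serial[0]}"
            log.append(
                {
                    "type": "tip",
                    "lineage": lineage,
                    "host": host_node.label,
                    "time": t_end,
                    "leaf": label,
                }
            )
            leaf = Node(label=label, length=t_end)
            return leaf
        # host speciation
        if rng.random() < params.p_cospeciation:
            counts["cospeciation"] += 1
            left_id, right_id = new_lineage(), new_lineage()
            log.append(
                {
                    "type": "cospeciation",
                    "lineage": lineage,
                    "host": host_node.label,
                    "time": t_end,
                    "daughters": [left_id, right_id],
                }
            )
            node = Node(length=t_end)
            node.add_child(evolve(left_id, host_node.children[0], t_end, True))
            node.add_child(evolve(right_id, host_node.children[1], t_end, True))
            return node
        counts["loss"] += 1
        followed = host_node.children[int(rng.integers(2))]
        log.append(
            {
                "type": "loss",
                "lineage": lineage,
                "host": host_node.label,
                "time": t_end,
                "followed": followed.label,
            }
        )
        return evolve(lineage, followed, t_end, True)

    root_lineage = new_lineage()
    symb_root = evolve(root_lineage, host.root, 0.0, False)
    _times_to_lengths(symb_root, 0.0)
    symbiont = PhyloTree(symb_root, rooted=True)
    links = AssociationMap(
        [(entry["host"], entry["leaf"]) for entry in log if entry["type"] == "tip"]
    )
    true_root = (
        symbiont.bipartition_of(symb_root.children[0]) if symb_root.children else None
    )
    return SimulatedCophylogeny(
        host=host,
        symbiont=symbiont,
        links=links,
        event_counts=counts,
        true_root_bipartition=true_root,
        event_log=log,
        params=params,
    )


def _times_to_lengths(node: Node, parent_time: float) -> None:
    own_time = node.length if node.length is not None else parent_time
    node.length = max(own_time - parent_time, 0.0)
    for child in node.children:
        _times_to_lengths(child, own_time)


def replay_event_log(log: list) -> PhyloTree:
    """Rebuild the symbiont tree from a recorded event log.

    Independent of the simulator's own construction path: the tree is grown
    purely from the logged branching events and tip records, so equality with
    the simulated tree certifies that the log is a complete account of the
    realised history.
    """
    by_lineage: dict = {}
    for entry in log:
        by_lineage.setdefault(entry["lineage"], []).append(entry)

    def build(lineage: int) -> Node:
        for entry in by_lineage.get(lineage, []):
            if entry["type"] in ("cospeciation", "duplication", "switch"):
                node = Node(length=entry["time"])
                left, right = entry["daughters"]
                node.add_child(build(left))
                node.add_child(build(right))
                return node
            if entry["type"] == "tip":
                return Node(label=entry["leaf"], length=entry["time"])
        raise ValidationError(f"event log is incomplete for lineage {lineage}")

    lineages_as_daughters = {
        d for e in log if "daughters" in e for d in e["daughters"]
    }
    roots = [l for l in by_lineage if l not in lineages_as_daughters]
    if len(roots) != 1:
        raise ValidationError("event log does not describe a single rooted history")
    root = build(roots[0])
    _times_to_lengths(root, 0.0)
    return PhyloTree(root, rooted=True)
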