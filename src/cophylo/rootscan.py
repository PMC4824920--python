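"""Rank candidate rootings of an unrooted symbiont tree by reconciliation cost.

When no outgroup can root a symbiont phylogeny reliably, an alternative is to
reroot it on every candidate edge, reconcile each rooted version against the
host tree under one shared cost regime, and rank the rootings by minimum
cost.  The argmin set (ties are reported, never broken) identifies the basal
symbiont lineage best supported by the coevolutionary history.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .associations import AssociationMap
from .errors import ValidationError
from .reconcile import CostRegime, Reconciliation, SolverConfig, TimeZones, solve_reconciliation
from .trees import PhyloTree, RootPlacement

__all__ = ["RootScanResult", "ScanEntry", "scan_roots", "compare_rooting_scenarios"]


@dataclass
class ScanEntry:
    name: str
    placement: RootPlacement
    cost: float
    event_counts: tuple  # (cospeciation, duplication, switch, loss)
    reconciliation: Reconciliation


@dataclass
class RootScanResult:
    """Per-candidate minimum costs, sorted ascending; ties share the minimum."""

    entries: list

    @property
    def min_cost(self) -> float:
        return min(e.cost for e in self.entries)

    @property
    def argmin(self) -> list:
        m = self.min_cost
        return [e for e in self.entries if e.cost <= m + 1e-9]

    def argmin_bipartitions(self) -> set:
        return {e.placement.bipartition for e in self.argmin}


def _resolve_clade_candidate(
    symbiont: PhyloTree, name: str, leaves: Sequence[str]
) -> RootPlacement:
    """The edge subtending the smallest clade containing exactly ``leaves``."""
    leafset = frozenset(str(l) for l in leaves)
    all_leaves = frozenset(symbiont.leaf_labels)
    missing = leafset - all_leaves
    if missing:
        raise ValidationError(
            f"candidate {name!r} names unknown leaves: {', '.join(sorted(missing))}"
        )
    for placement in symbiont.enumerate_rootings():
        if placement.bipartition == leafset or (all_leaves - placement.bipartition) == leafset:
            return RootPlacement(leafset)
    raise ValidationError(
        f"candidate {name!r} is not monophyletic in the unrooted symbiont tree: "
        f"no edge separates {{{', '.join(sorted(leafset))}}} from the remaining leaves"
    )


def scan_roots(
    symbiont_unrooted: PhyloTree,
    host: PhyloTree,
    links: AssociationMap,
    regime: CostRegime = CostRegime(),
    zones: Optional[TimeZones] = None,
    candidates: Union[str, dict, None] = "all-edges",
    config: SolverConfig = SolverConfig(),
) -> RootScanResult:
    """Reroot the symbiont tree at each candidate and reconcile exactly.

    ``candidates`` is either ``"all-edges"`` (one candidate per edge of the
    unrooted tree) or a mapping of candidate names to clade-defining leaf
    sets; a clade candidate resolves to the edge subtending the smallest
    clade containing exactly those leaves and errors if that leaf set is not
    monophyletic.  Results are sorted by ascending cost (stable, hence
    deterministic); equal-cost candidates are all reported as co-optimal.
    """
    if symbiont_unrooted.rooted:
        raise ValidationError("scan_roots expects an unrooted symbiont tree")
    if candidates is None or candidates == "all-edges" or candidates == "all":
        named = [
            (f"edge{{{','.join(sorted(p.bipartition))}}}", p)
            for p in symbiont_unrooted.enumerate_rootings()
        ]
    else:
        named = [
            (str(name), _resolve_clade_candidate(symbiont_unrooted, str(name), leaves))
            for name, leaves in candidates.items()
        ]
    if not named:
        raise ValidationError("no rooting candidates to evaluate")
    entries = []
    for name, placement in named:
        rooted = symbiont_unrooted.reroot_at(placement)
        rec = solve_reconciliation(host, rooted, links, regime, zones, config)
        entries.append(
            ScanEntry(
                name=name,
                placement=placement,
                cost=rec.total_cost,
                event_counts=rec.event_counts(),
                reconciliation=rec,
            )
        )
    entries.sort(key=lambda e: (e.cost, e.name))
    return RootScanResult(entries)


def compare_rooting_scenarios(
    result: RootScanResult, labels: Optional[dict] = None
) -> pd.DataFrame:
    """Ranked table of candidates with costs and deltas from the minimum.

    ``labels`` optionally renames candidates (e.g. supergroup names).  The
    returned frame has one row per candidate with columns name, cost,
    delta_cost, co_optimal and the four event counts; delta_cost is always
    nonnegative and at least one row has delta_cost == 0.
    """
    if not result.entries:
        raise ValidationError("empty root-scan result")
    m = result.min_cost
    rows = []
    for e in result.entries:
        c, d, s, l = e.event_counts
        rows.append(
            {
                "name": (labels or {}).get(e.name, e.name),
                "cost": e.cost,
                "delta_cost": e.cost - m,
                "co_optimal": e.cost <= m + 1e-9,
                "cospeciations": c,
                "duplications": d,
                "switches": s,
                "losses": l,
            }
        )
    return pd.DataFrame(rows)
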