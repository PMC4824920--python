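"""Procrustes global-fit congruence test between host and symbiont phylogenies.

The procedure follows the distance-based global-fit approach widely used for
cophylogenetic data: each tree's patristic distance matrix is embedded by
principal coordinates analysis (PCoA); the two point configurations are
expanded to one row per host-symbiont link; and the symbiont configuration is
superimposed onto the host configuration by least-squares Procrustes analysis
(translation, rotation with reflection permitted, and a least-squares scale
factor, since the two trees are in different substitution-rate units).

The residual sum of squares of that superimposition, m2 (often written m2_XY),
is inversely proportional to topological congruence.  Its significance is
assessed by permuting the association matrix; each individual link's
contribution is assessed by a leave-one-link-out jackknife of its squared
residual with a one-sided upper 95% confidence bound.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .associations import AssociationMap
from .errors import ValidationError
from .trees import DistanceMatrix, PhyloTree

__all__ = [
    "PcoCoordinates",
    "ProcrustesFit",
    "PACoResult",
    "pcoa",
    "procrustes_superimpose",
    "paco_global_fit",
    "jackknife_link_residuals",
]

_EIG_TOL = 1e-10


@dataclass
class PcoCoordinates:
    """Principal-coordinate embedding of a distance matrix.

    Axes are ordered by decreasing eigenvalue and axes with eigenvalues at or
    below numerical tolerance are dropped, so whenever the input matrix is
    Euclidean-embeddable the pairwise row distances reproduce it exactly.
    """

    labels: tuple
    coordinates: np.ndarray  # (n taxa, n retained axes)
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, descending

    def row(self, label: str) -> np.ndarray:
        return self.coordinates[self.labels.index(label)]


@dataclass
class ProcrustesFit:
    """Least-squares superimposition of configuration Y onto X."""

    m2: float
    residuals: np.ndarray  # per-row squared residuals, sums to m2
    rotation: np.ndarray
    scale: float
    translation: np.ndarray


@dataclass
class PACoResult:
    fit: ProcrustesFit
    p_value: float
    n_permutations: int
    seed: int
    permutation_scheme: str
    links: list
    jackknife: Optional[list] = None  # list of (estimate, upper95) per link


def pcoa(d: DistanceMatrix, correction: str = "none") -> PcoCoordinates:
    """Principal coordinates analysis (Gower double-centering + eigh).

    ``correction`` handles non-Euclidean matrices: ``"none"`` simply drops
    negative-eigenvalue axes; ``"lingoes"`` adds a constant to all squared
    off-diagonal distances; ``"cailliez"`` adds a constant to all off-diagonal
    distances.  Patristic matrices are tree-additive and typically embeddable,
    so no correction is the default.
    """
    if correction not in ("none", "lingoes", "cailliez"):
        raise ValidationError(f"unknown PCoA correction {correction!r}")
    dm = np.asarray(d.values, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-9):
        raise ValidationError("PCoA requires a symmetric distance matrix")
    vals, vecs = _gower_eig(dm)
    if correction != "none" and vals[-1] < -_EIG_TOL * max(1.0, abs(vals[0])):
        if correction == "lingoes":
            c = abs(vals[-1])
            d2 = dm**2 + 2.0 * c
            np.fill_diagonal(d2, 0.0)
            vals, vecs = _gower_eig(np.sqrt(d2))
        else:  # cailliez
            c = _cailliez_constant(dm)
            dc = dm + c
            np.fill_diagonal(dc, 0.0)
            vals, vecs = _gower_eig(dc)
    tol = _EIG_TOL * max(1.0, abs(vals[0]) if vals.size else 1.0)
    keep = vals > tol
    vals = vals[keep]
    coords = vecs[:, keep] * np.sqrt(vals)
    return PcoCoordinates(tuple(d.labels), coords, vals)


def _gower_eig(dm: np.ndarray):
    n = dm.shape[0]
    a = -0.5 * dm**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    vals, vecs = np.linalg.eigh(centered)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def _cailliez_constant(dm: np.ndarray) -> float:
    n = dm.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    d1 = j @ (-0.5 * dm**2) @ j
    d2 = j @ (-0.5 * dm) @ j
    block = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    eigs = np.linalg.eigvals(block)
    return float(np.max(eigs.real))


def procrustes_superimpose(x: np.ndarray, y: np.ndarray) -> ProcrustesFit:
    """Superimpose configuration ``y`` onto ``x`` by least squares.

    Both arrays must have one row per host-symbiont link (host row paired with
    its linked symbiont row); the narrower configuration is zero-padded to
    equal width, never truncated.  The fitted transform is translation +
    rotation (reflection permitted) + uniform scaling; m2 is the residual sum
    of squares and ``residuals`` its per-row decomposition in link order.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValidationError(
            f"row-count mismatch: x has {x.shape[0]} rows, y has {y.shape[0]}"
        )
    width = max(x.shape[1], y.shape[1])
    x = _pad(x, width)
    y = _pad(y, width)
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    ynorm2 = float((yc**2).sum())
    if ynorm2 <= 0.0:
        # degenerate: all symbiont points coincide; best fit collapses y onto
        # the host centroid
        rotation = np.eye(width)
        scale = 0.0
        fitted = np.zeros_like(yc)
    else:
        u, s, vt = np.linalg.svd(yc.T @ xc)
        rotation = u @ vt
        scale = float(s.sum() / ynorm2)
        fitted = scale * yc @ rotation
    diff = xc - fitted
    residuals = (diff**2).sum(axis=1)
    translation = mx - (scale * my @ rotation if ynorm2 > 0 else np.zeros(width))
    return ProcrustesFit(
        m2=float(residuals.sum()),
        residuals=residuals,
        rotation=rotation,
        scale=scale,
        translation=translation,
    )


def _pad(arr: np.ndarray, width: int) -> np.ndarray:
    if arr.shape[1] == width:
        return arr
    out = np.zeros((arr.shape[0], width))
    out[:, : arr.shape[1]] = arr
    return out


def _expanded_configurations(
    host: PhyloTree, symbiont: PhyloTree, links: AssociationMap, correction: str = "none"
):
    links.validate_against(host, symbiont)
    hp = pcoa(host.patristic_distances(), correction=correction)
    sp = pcoa(symbiont.patristic_distances(), correction=correction)
    hidx = {l: i for i, l in enumerate(hp.labels)}
    sidx = {l: i for i, l in enumerate(sp.labels)}
    hrows = np.array([hidx[h] for h, _ in links])
    srows = np.array([sidx[s] for _, s in links])
    return hp.coordinates[hrows], sp.coordinates[srows], hp, sp


def _fit_links(hcoords, scoords, hrow_idx, srow_idx) -> ProcrustesFit:
    return procrustes_superimpose(hcoords[hrow_idx], scoords[srow_idx])


def paco_global_fit(
    host: PhyloTree,
    symbiont: PhyloTree,
    links: AssociationMap,
    n_perm: int = 100_000,
    seed: int = 0,
    permutation_scheme: str = "full-shuffle",
    correction: str = "none",
    compute_jackknife: bool = False,
) -> PACoResult:
    """Global-fit congruence test with a permutation null distribution.

    The observed m2 comes from the unpermuted links.  Null m2 values come from
    randomised association matrices: ``"full-shuffle"`` (default) redraws the
    binary association matrix uniformly while preserving the total number of
    links; ``"row-shuffle"`` permutes the symbiont column of the link list,
    preserving each host's link count.  The p-value uses the add-one rule
    p = (1 + #{m2_perm <= m2_obs}) / (n_perm + 1), so it always lies in (0, 1].
    Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if permutation_scheme not in ("full-shuffle", "row-shuffle"):
        raise ValidationError(f"unknown permutation scheme {permutation_scheme!r}")
    xh, ys, hp, sp = _expanded_configurations(host, symbiont, links, correction)
    observed = procrustes_superimpose(xh, ys)

    rng = np.random.default_rng(seed)
    n_hosts, n_symb = len(hp.labels), len(sp.labels)
    n_links = len(links)
    count_le = 0
    if permutation_scheme == "row-shuffle":
        hidx = {l: i for i, l in enumerate(hp.labels)}
        sidx = {l: i for i, l in enumerate(sp.labels)}
        host_rows = np.array([hidx[h] for h, _ in links])
        symb_rows = np.array([sidx[s] for _, s in links])
        for _ in range(n_perm):
            perm = rng.permutation(n_links)
            fit = procrustes_superimpose(
                hp.coordinates[host_rows], sp.coordinates[symb_rows[perm]]
            )
            if fit.m2 <= observed.m2:
                count_le += 1
    else:
        n_cells = n_hosts * n_symb
        for _ in range(n_perm):
            cells = rng.choice(n_cells, size=n_links, replace=False)
            hr, sr = np.divmod(cells, n_symb)
            fit = procrustes_superimpose(hp.coordinates[hr], sp.coordinates[sr])
            if fit.m2 <= observed.m2:
                count_le += 1
    p_value = (1 + count_le) / (n_perm + 1)

    result = PACoResult(
        fit=observed,
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
        permutation_scheme=permutation_scheme,
        links=list(links),
    )
    if compute_jackknife:
        result.jackknife = jackknife_link_residuals(host, symbiont, links, correction)
    return result


def jackknife_link_residuals(
    host: PhyloTree,
    symbiont: PhyloTree,
    links: AssociationMap,
    correction: str = "none",
) -> list:
    """Leave-one-link-out jackknife of each link's squared residual.

    For link i, every deletion j != i yields the pseudovalue
    ``n * r_full_i - (n - 1) * r_minus_j_i``.  The estimate is the mean
    pseudovalue (clipped below at 0) and the upper bound adds
    t(0.95, n-1) standard errors, matching a one-sided 95% confidence
    interval.  Values are keyed by link, so input order does not affect them.
    """
    n = len(links)
    if n < 3:
        raise ValidationError("jackknife requires at least 3 links")
    xh, ys, _, _ = _expanded_configurations(host, symbiont, links, correction)
    full = procrustes_superimpose(xh, ys).residuals
    # pseudo[j, i] = pseudovalue of link i from deleting link j
    pseudo = np.full((n, n), np.nan)
    keep_idx = np.arange(n)
    for j in range(n):
        keep = keep_idx[keep_idx != j]
        fit = procrustes_superimpose(xh[keep], ys[keep])
        pseudo[j, keep] = n * full[keep] - (n - 1) * fit.residuals
    t_crit = float(stats.t.ppf(0.95, n - 1))
    out = []
    for i in range(n):
        pv = pseudo[:, i]
        pv = pv[~np.isnan(pv)]  # the n-1 deletions that retain link i
        estimate = float(pv.mean())
        if pv.size > 1 and np.ptp(pv) > 0:
            se = float(pv.std(ddof=1) / np.sqrt(pv.size))
        else:
            se = 0.0
        estimate = max(estimate, 0.0)
        upper = max(estimate + t_crit * se, 0.0)
        out.append((estimate, upper))
    return out
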