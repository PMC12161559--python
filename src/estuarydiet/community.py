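"""Multivariate diet comparisons: Bray-Curtis, NMDS, ANOSIM, SIMPER,
and species-vector fitting for ordination overlays.

The input is a diet matrix: rows are groups (e.g. site x year x length
bin), columns are taxa, cells are %IRI values (each row sums to 100).
All machinery here is rank/percentage based, which is why Bray-Curtis is
the distance of choice.

Implementation notes
--------------------
* NMDS minimizes Kruskal's stress-1,
  sqrt(sum (dhat_ij - dstar_ij)^2 / sum dhat_ij^2), where dhat are
  configuration distances and dstar the isotonic (pool-adjacent-violators)
  regression of dhat on the rank order of the input dissimilarities.
  Optimization is gradient descent with a step-halving line search, so the
  stress of accepted iterates never increases; restarts start from
  classical (Torgerson) scaling plus seeded jitter.  The returned
  configuration is centered and rotated to its principal axes, so results
  are comparable across runs up to reflection.
* ANOSIM uses midranks for ties and the add-one permutation p-value
  (1 + #{R_perm >= R_obs}) / (1 + n_permutations), which cannot be zero.
  Pairwise tests re-rank within each pair's submatrix and apply a
  Bonferroni correction (p times the number of pairs, capped at 1).
* SIMPER decomposes the average between-group Bray-Curtis dissimilarity
  into per-taxon contributions; the reported head list is the smallest
  prefix of taxa (sorted by descending contribution) reaching 70% of the
  total.  No significance test is attached: SIMPER is descriptive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import isotonic_regression

from .metrics import composition
from .records import Dataset

__all__ = [
    "diet_matrix",
    "bray_curtis",
    "nmds",
    "NmdsResult",
    "anosim",
    "pairwise_anosim",
    "AnosimResult",
    "simper",
    "SimperResult",
    "fit_species_vectors",
]


def diet_matrix(
    ds: Dataset,
    grouping: Sequence[str] = ("site", "year"),
    length_scheme: str | None = None,
) -> pd.DataFrame:
    """Groups x taxa matrix of %IRI values (rows sum to 100).

    ``length_scheme`` of "model" or "ordination" appends the corresponding
    length-bin column to the grouping.
    """
    grouping = list(grouping)
    if length_scheme == "model":
        grouping.append("length_bin")
    elif length_scheme == "ordination":
        grouping.append("length_bin_ordination")
    elif length_scheme is not None:
        raise ValueError(f"unknown length scheme: {length_scheme!r}")
    comp = composition(ds, grouping)
    mat = comp.pivot_table(
        index=grouping, columns="taxon", values="iri_pct", fill_value=0.0
    )
    mat.columns.name = None
    return mat


def _as_array(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if (a < 0).any():
        raise ValueError("diet matrix cells must be non-negative")
    return a


def bray_curtis(m: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Pairwise Bray-Curtis dissimilarity d(a,b) = sum|a-b| / sum(a+b).

    Symmetric, zero diagonal, values in [0, 1]; a pair of all-zero rows
    has d = 0 by convention.
    """
    a = _as_array(m)
    diff = np.abs(a[:, None, :] - a[None, :, :]).sum(axis=2)
    tot = (a[:, None, :] + a[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(d, index=m.index, columns=m.index)
    return d


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame | np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    n_iter: int = 0
    #: stress after each accepted line-search step of the best restart
    #: (non-increasing by construction)
    stress_trace: tuple[float, ...] = ()

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float)


def _condensed(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return _condensed(np.sqrt((diff**2).sum(axis=2)))


def _stress1(dhat: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Stress-1 and the isotonic disparities for configuration distances
    ``dhat`` against the rank order of the target dissimilarities.

    Ties in the target are treated with Kruskal's primary approach: within
    a tie block the configuration distances impose no order constraint
    (they are pre-sorted ascending, so the isotonic fit is free there).
    """
    order = np.lexsort((dhat, target))
    dstar = np.empty_like(dhat)
    dstar[order] = isotonic_regression(dhat[order])
    denom = float((dhat**2).sum())
    if denom == 0:
        return 0.0, dstar
    return math.sqrt(float(((dhat - dstar) ** 2).sum()) / denom), dstar


def _stress_gradient(
    x: np.ndarray, dhat: np.ndarray, dstar: np.ndarray, stress: float
) -> np.ndarray:
    """Gradient of stress-1 w.r.t. the configuration, holding the isotonic
    disparities fixed (valid a.e. because isotonic regression is a
    least-squares projection)."""
    n, k = x.shape
    if stress == 0:
        return np.zeros_like(x)
    s_star = float(((dhat - dstar) ** 2).sum())
    t_star = float((dhat**2).sum())
    # dS/d dhat_ij per pair
    safe = np.where(dhat > 0, dhat, 1.0)
    coeff = (dhat - dstar) / (s_star if s_star > 0 else 1.0) - dhat / t_star
    coeff = stress * coeff / safe
    iu, ju = np.triu_indices(n, k=1)
    grad = np.zeros_like(x)
    delta = x[iu] - x[ju]  # (npairs, k)
    contrib = coeff[:, None] * delta
    np.add.at(grad, iu, contrib)
    np.add.at(grad, ju, -contrib)
    return grad


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling of a squared-dissimilarity matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _principal_axes(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt.T


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = 0,
) -> NmdsResult:
    """Nonmetric multidimensional scaling by stress-1 minimization.

    Returns the best configuration over ``n_restarts`` seeded starts
    (classical scaling, then jittered variants), centered and rotated to
    principal axes.  ``converged`` is False if the best restart hit
    ``max_iter`` before the relative stress change fell below ``tol``.
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    rng = np.random.default_rng(seed)
    target = _condensed(dm)

    base = _classical_scaling(dm, k)
    scale = max(base.std(), 1e-3)

    best_x, best_stress, best_iters, best_conv = None, np.inf, 0, False
    best_trace: tuple[float, ...] = ()
    for restart in range(n_restarts):
        x = base.copy()
        if restart > 0:
            x = x + rng.normal(scale=0.25 * scale, size=x.shape)
        dhat = _config_distances(x)
        stress, dstar = _stress1(dhat, target)
        trace = [stress]
        step = 0.1
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            grad = _stress_gradient(x, dhat, dstar, stress)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0 or stress == 0:
                converged = True
                break
            direction = -grad / gnorm
            accepted = False
            trial_step = step
            for _ in range(30):  # step-halving line search
                x_new = x + trial_step * scale * direction
                dhat_new = _config_distances(x_new)
                stress_new, dstar_new = _stress1(dhat_new, target)
                if stress_new < stress:
                    accepted = True
                    break
                trial_step *= 0.5
            if not accepted:
                converged = True
                break
            rel = (stress - stress_new) / max(stress, 1e-300)
            x, dhat, dstar, stress = x_new, dhat_new, dstar_new, stress_new
            trace.append(stress)
            step = min(trial_step * 2.0, 1.0)
            if rel < tol:
                converged = True
                break
        if stress < best_stress - 1e-12:
            best_x, best_stress = x, stress
            best_iters, best_conv = it, converged
            best_trace = tuple(trace)

    coords = _principal_axes(best_x)
    if isinstance(d, pd.DataFrame):
        coords = pd.DataFrame(
            coords, index=d.index, columns=[f"axis{i + 1}" for i in range(k)]
        )
    return NmdsResult(
        coordinates=coords,
        stress=float(best_stress),
        n_restarts=n_restarts,
        converged=best_conv,
        n_iter=best_iters,
        stress_trace=best_trace,
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    method: str = "permutation"


def _anosim_r(cond_ranks: np.ndarray, labels: np.ndarray, n: int) -> float:
    iu, ju = np.triu_indices(n, k=1)
    within = labels[iu] == labels[ju]
    r_between = cond_ranks[~within].mean()
    r_within = cond_ranks[within].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(
    d: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
    method: str = "permutation",
) -> AnosimResult:
    """Analysis of similarities: rank-based test of between- vs
    within-group dissimilarity.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with midranks for ties.  ``method='permutation'`` draws seeded uniform
    label permutations and reports the add-one p-value;
    ``method='exact'`` enumerates every distinct label assignment (only
    feasible for small n) and reports the exact tail proportion.
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    labels = np.asarray(groups)
    if len(labels) != n:
        raise ValueError("groups length must match matrix size")
    if len(np.unique(labels)) < 2:
        raise ValueError("anosim requires at least two groups")
    cond = _condensed(dm)
    ranks = rankdata(cond)  # midranks
    r_obs = _anosim_r(ranks, labels, n)

    if method == "exact":
        perms = set(itertools.permutations(labels))
        count = sum(
            _anosim_r(ranks, np.asarray(p), n) >= r_obs - 1e-12 for p in perms
        )
        return AnosimResult(
            r=float(r_obs),
            p_value=count / len(perms),
            n_permutations=len(perms),
            method="exact",
        )
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _anosim_r(ranks, lab, n) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(
        r=float(r_obs), p_value=p, n_permutations=n_permutations
    )


def pairwise_anosim(
    d: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """ANOSIM on every group pair's submatrix (re-ranked within the
    submatrix), with Bonferroni-adjusted p-values."""
    dm = np.asarray(d, dtype=float)
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    pairs = list(itertools.combinations(uniq, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        mask = (labels == a) | (labels == b)
        sub = dm[np.ix_(mask, mask)]
        res = anosim(sub, labels[mask], n_permutations=n_permutations, seed=rng)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "r": res.r,
                "p_value": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SIMPER


@dataclass
class SimperResult:
    pair: tuple
    table: pd.DataFrame  # taxon, contribution, contribution_pct, cumulative_pct
    mean_dissimilarity: float
    head_taxa: tuple[str, ...]  # smallest prefix reaching >= 70% cumulative

    @property
    def contributions(self) -> pd.Series:
        return self.table.set_index("taxon")["contribution"]


def simper(
    m: pd.DataFrame,
    groups: Sequence,
    pair: tuple,
    cutoff_pct: float = 70.0,
) -> SimperResult:
    """Decompose mean between-group Bray-Curtis dissimilarity by taxon.

    For each between-group row pair (a, b) the per-taxon contribution is
    |a_i - b_i| / sum_j (a_j + b_j); averaging over all between pairs
    gives contributions that sum exactly to the mean between-group
    dissimilarity.  ``head_taxa`` lists the top taxa reaching the cutoff
    (default 70%) of the total.
    """
    labels = np.asarray(groups)
    a_lab, b_lab = pair
    xa = _as_array(m)[labels == a_lab]
    xb = _as_array(m)[labels == b_lab]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError(f"empty group in pair {pair}")
    taxa = list(m.columns) if isinstance(m, pd.DataFrame) else list(
        range(np.asarray(m).shape[1])
    )
    # (na, nb, taxa) pairwise pieces
    diff = np.abs(xa[:, None, :] - xb[None, :, :])
    tot = (xa[:, None, :] + xb[None, :, :]).sum(axis=2, keepdims=True)
    tot = np.where(tot > 0, tot, 1.0)
    contrib = (diff / tot).mean(axis=(0, 1))
    total = contrib.sum()
    pct = 100.0 * contrib / total if total > 0 else contrib * 0.0
    order = np.argsort(-contrib, kind="stable")
    cum = np.cumsum(pct[order])
    n_head = int(np.searchsorted(cum, cutoff_pct - 1e-12) + 1) if total > 0 else 0
    table = pd.DataFrame(
        {
            "taxon": [taxa[i] for i in order],
            "contribution": contrib[order],
            "contribution_pct": pct[order],
            "cumulative_pct": cum,
        }
    )
    return SimperResult(
        pair=(a_lab, b_lab),
        table=table,
        mean_dissimilarity=float(total),
        head_taxa=tuple(table["taxon"].iloc[:n_head]),
    )


# ---------------------------------------------------------------------------
# Species vectors (ordination overlay)


def fit_species_vectors(
    m: pd.DataFrame,
    ordination: NmdsResult,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Least-squares fit of each taxon column onto the ordination space.

    For each taxon the direction is the unit vector of regression
    coefficients of the (centered) taxon values on the ordination axes;
    strength is the squared multiple correlation R^2; the p-value is a
    seeded permutation test shuffling rows.  Taxa with p <= alpha are
    flagged significant.  A constant column gets R^2 = 0 and p = 1.
    """
    x = ordination.points
    x = x - x.mean(axis=0)
    vals = np.asarray(m, dtype=float)
    taxa = list(m.columns) if isinstance(m, pd.DataFrame) else list(
        range(vals.shape[1])
    )
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    xtx_inv = np.linalg.pinv(x.T @ x)

    def r2_and_beta(y: np.ndarray) -> tuple[float, np.ndarray]:
        yc = y - y.mean()
        ss_tot = float((yc**2).sum())
        if ss_tot == 0:
            return 0.0, np.zeros(x.shape[1])
        beta = xtx_inv @ (x.T @ yc)
        ss_fit = float((x @ beta * yc).sum())
        return max(ss_fit / ss_tot, 0.0), beta

    rows = []
    for j, taxon in enumerate(taxa):
        y = vals[:, j].astype(float)
        r2, beta = r2_and_beta(y)
        if r2 == 0.0:
            p = 1.0
        else:
            count = 0
            yp = y.copy()
            for _ in range(n_permutations):
                rng.shuffle(yp)
                if r2_and_beta(yp)[0] >= r2 - 1e-12:
                    count += 1
            p = (1 + count) / (1 + n_permutations)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        rows.append(
            {
                "taxon": taxon,
                **{f"axis{i + 1}": direction[i] for i in range(x.shape[1])},
                "r_squared": r2,
                "p_value": p,
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows)
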