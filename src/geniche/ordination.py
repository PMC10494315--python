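"""Constrained ordination of adaptive allele frequencies.

Hellinger-transform the site x locus frequency table, build spatial
eigenvector predictors (PCNM: principal coordinates of a truncated
great-circle neighbour matrix), prune collinear predictors, and fit a
redundancy analysis (RDA) with forward selection under permutation tests
and the double stopping rule (per-step alpha plus the global-model
adjusted R-squared ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .io import log

EARTH_RADIUS_KM = 6371.0


@dataclass
class RDAResult:
    selected: list[str]
    step_pvalues: list[float]
    r2: float
    r2_adj: float
    axes: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    model_p: float = float("nan")
    n_permutations: int = 0
    stopped_because: str = ""

    def __post_init__(self) -> None:
        if self.r2_adj > self.r2 + 1e-12:
            raise ValueError("adjusted R2 cannot exceed R2")


def hellinger_transform(F: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize to proportions, then square-root; zero rows stay zero."""
    X = F.to_numpy(dtype=float)
    rs = X.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return pd.DataFrame(np.sqrt(X / rs), index=F.index, columns=F.columns)


def haversine_matrix(lon, lat) -> np.ndarray:
    """Great-circle distance matrix in km (Earth radius 6371 km)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pcnm_eigenvectors(coords: pd.DataFrame, truncation: float | None = None):
    """Spatial eigenvectors from a truncated neighbour distance matrix.

    Distances beyond the truncation threshold (default: the longest edge
    of the minimum spanning tree of the great-circle distance matrix) are
    replaced by four times the threshold; a principal coordinates analysis
    of the result yields the eigenvectors, of which those with positive
    eigenvalues are returned in decreasing eigenvalue order.

    Returns ``(vectors, eigenvalues)`` with columns PCNM1, PCNM2, ...
    """
    D = haversine_matrix(coords["lon"], coords["lat"])
    n = D.shape[0]
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    Dt = np.where(D > truncation, 4.0 * truncation, D)
    np.fill_diagonal(Dt, 0.0)
    # classical PCoA (Gower double-centering)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dt**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = 1e-8 * max(abs(w).max(), 1.0)
    pos = w > tol
    vec = V[:, pos] * np.sqrt(w[pos])
    cols = [f"PCNM{i + 1}" for i in range(vec.shape[1])]
    return pd.DataFrame(vec, columns=cols, index=coords.index), w[pos]


def collinearity_filter(env: pd.DataFrame, predictors: list[str], r_max: float = 0.70):
    """Greedy collinearity pruning in a stated priority order.

    Predictors are visited in the order given; one is dropped if its
    absolute Pearson correlation with an already-retained predictor
    exceeds ``r_max``.  Returns ``(retained, dropped_for)`` where
    ``dropped_for`` maps each dropped name to the retained name that
    caused the drop.
    """
    retained: list[str] = []
    dropped_for: dict[str, str] = {}
    for name in predictors:
        x = env[name].to_numpy(dtype=float)
        culprit = None
        for kept in retained:
            r = np.corrcoef(x, env[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > r_max:
                culprit = kept
                break
        if culprit is None:
            retained.append(name)
        else:
            dropped_for[name] = culprit
    if dropped_for:
        log.info("collinearity filter dropped %s", dropped_for)
    return retained, dropped_for


def _rda_r2(Yc: np.ndarray, X: np.ndarray) -> float:
    """RDA R2: share of total variance captured by the fitted values."""
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    ss_tot = (Yc**2).sum()
    if ss_tot == 0:
        return 0.0
    return float((fitted**2).sum() / ss_tot)


def ezekiel_adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel correction: 1 - (1 - R2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return float("-inf")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _perm_p(Yc, X_base, x_new, n_perm, rng) -> float:
    """Permutation p for adding x_new given X_base (residual permutation)."""
    n = Yc.shape[0]
    if X_base.shape[1] > 0:
        Xb = X_base - X_base.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xb, Yc, rcond=None)
        resid = Yc - Xb @ beta
        base_r2 = _rda_r2(Yc, X_base)
    else:
        resid = Yc
        base_r2 = 0.0
    X_full = np.column_stack([X_base, x_new]) if X_base.shape[1] else x_new.reshape(-1, 1)
    obs_gain = _rda_r2(Yc, X_full) - base_r2
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yc - resid + resid[perm]
        gain = _rda_r2(Yp, X_full) - _rda_r2(Yp, X_base) if X_base.shape[1] else _rda_r2(Yp, X_full)
        if gain >= obs_gain - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


def rda_forward_select(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> RDAResult:
    """Forward selection of RDA predictors under the double stopping rule.

    At each step the candidate maximizing the gain in R2 is tested by
    ``n_perm`` permutations of the current-model residuals; it enters if
    its p-value is at most ``alpha`` and the running model's adjusted R2
    does not exceed the global (all-predictor) adjusted R2.  Returns the
    fitted parsimonious model with canonical axes and a permutation p for
    the whole selected model.
    """
    rng = np.random.default_rng(seed)
    Yc = Y.to_numpy(dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    n = Yc.shape[0]
    cand = list(X.columns)
    Xall = X.to_numpy(dtype=float)
    global_adj = ezekiel_adjusted_r2(_rda_r2(Yc, Xall), n, Xall.shape[1])
    if not np.isfinite(global_adj):
        # saturated global model: the adjusted-R2 ceiling is uninformative
        log.info("forward selection: global model saturated, alpha rule only")
        global_adj = np.inf

    selected: list[str] = []
    pvals: list[float] = []
    stopped = "no candidate passed"
    while cand:
        if n <= len(selected) + 2:
            stopped = "saturated model"
            log.warning("forward selection stopped: saturated with %d predictors", len(selected))
            break
        X_base = X[selected].to_numpy(dtype=float) if selected else np.empty((n, 0))
        gains = []
        for name in cand:
            X_try = np.column_stack([X_base, X[name].to_numpy(dtype=float)])
            gains.append(_rda_r2(Yc, X_try))
        best = int(np.argmax(gains))
        name = cand[best]
        p = _perm_p(Yc, X_base, X[name].to_numpy(dtype=float), n_perm, rng)
        if not selected:
            # the first entrant is the maximum over all candidates: Sidak-
            # correct its p for the candidate count to control the
            # selection-bias false-start rate
            p = 1.0 - (1.0 - p) ** len(cand)
        if p > alpha:
            stopped = f"{name} p={p:.4f} > alpha"
            break
        new_adj = ezekiel_adjusted_r2(gains[best], n, len(selected) + 1)
        if new_adj > global_adj + 1e-12:
            stopped = f"{name} would exceed global adjusted R2"
            break
        selected.append(name)
        pvals.append(p)
        cand.remove(name)

    Xs = X[selected].to_numpy(dtype=float) if selected else np.empty((n, 0))
    r2 = _rda_r2(Yc, Xs) if selected else 0.0
    r2_adj = ezekiel_adjusted_r2(r2, n, len(selected)) if selected else 0.0
    axes = np.empty((n, 0))
    model_p = float("nan")
    if selected:
        Xc = Xs - Xs.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
        U, s, _ = np.linalg.svd(fitted, full_matrices=False)
        k = min(len(selected), (s > 1e-10).sum())
        axes = U[:, :k] * s[:k]
        # whole-model permutation test
        obs = r2
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _rda_r2(Yc[perm], Xs) >= obs - 1e-15:
                count += 1
        model_p = (count + 1) / (n_perm + 1)
    return RDAResult(selected, pvals, r2, r2_adj, axes, model_p, n_perm, stopped)
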