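"""The genomic-niche index: combining suitability change and genomic offset.

Suitability change (absolute values, decrease-focused) and genomic offset
are min-max scaled to [0, 0.9] and combined cellwise into the weighted
geometric mean ``A = B**alpha * C**(1 - alpha)``.  The weight ``alpha``
is chosen to minimize the total deviation of the index from both of its
ingredients, ``D(alpha) = sum((A - B)**2 + (A - C)**2)``, using an
artificial bee colony search over [0, 1].  (An L1 variant is available,
but it is degenerate: the geometric mean always lies between B and C, so
``|A - B| + |A - C|`` collapses to ``|B - C|`` for every alpha.)  Smaller
``A`` means a smaller habitat-suitability loss combined with a smaller
required genomic adjustment — i.e. a higher overall invasion risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import log
from .stats import bh_adjust, rank_sum_test


@dataclass
class ClusterComparison:
    table: pd.DataFrame  # comparison, group_a, group_b, n_a, n_b, W, p, p_adj

    def __post_init__(self) -> None:
        t = self.table
        if (t["p_adj"] + 1e-12 < t["p"]).any():
            raise ValueError("adjusted p cannot be below raw p")


def scale_to_range(values, lo: float = 0.0, hi: float = 0.9, absolute: bool = False) -> np.ndarray:
    """Min-max scale to [lo, hi]; optionally take absolute values first.

    A constant vector maps to ``lo`` (logged): it carries no contrast.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    if absolute:
        v = np.abs(v)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        log.warning("scale_to_range: constant input, mapping all values to %s", lo)
        return np.full_like(v, lo)
    return lo + (v - vmin) / (vmax - vmin) * (hi - lo)


def genomic_niche_index(B, C, alpha: float) -> np.ndarray:
    """Weighted geometric mean A = B**alpha * C**(1-alpha), cellwise."""
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if (B < 0).any() or (C < 0).any():
        raise ValueError("B and C must be nonnegative")
    alpha = float(np.clip(alpha, 0.0, 1.0))
    if alpha == 0.0:
        return C.copy()
    if alpha == 1.0:
        return B.copy()
    return B**alpha * C ** (1.0 - alpha)


def deviation(B, C, alpha: float, objective: str = "l2") -> float:
    """Total deviation of the index from its two ingredients."""
    A = genomic_niche_index(B, C, alpha)
    if objective == "l1":
        return float(np.sum(np.abs(A - B) + np.abs(A - C)))
    if objective == "l2":
        return float(np.sum((A - B) ** 2 + (A - C) ** 2))
    raise ValueError(f"unknown objective {objective!r}")


def optimize_alpha(
    B,
    C,
    seed: int = 0,
    colony: int = 20,
    limit: int = 50,
    max_iter: int = 200,
    objective: str = "l2",
) -> tuple[float, float]:
    """Artificial bee colony minimization of the deviation over alpha in [0, 1].

    Standard ABC: each of ``colony`` food sources is an alpha value;
    employed bees perturb their source toward a random partner, onlooker
    bees re-sample sources with fitness-proportional probabilities, and a
    source abandoned after ``limit`` stagnant trials is replaced by a
    scout's uniform draw.  Returns ``(alpha*, D(alpha*))``.
    """
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    if B.size == 0 or B.shape != C.shape:
        raise ValueError("B and C must be nonempty and the same length")
    rng = np.random.default_rng(seed)
    obj = lambda a: deviation(B, C, a, objective)

    pos = rng.uniform(0.0, 1.0, colony)
    val = np.array([obj(a) for a in pos])
    trials = np.zeros(colony, dtype=int)
    best_a = float(pos[np.argmin(val)])
    best_v = float(val.min())

    def try_move(i: int) -> None:
        nonlocal best_a, best_v
        k = rng.integers(colony - 1)
        k = k if k < i else k + 1
        phi = rng.uniform(-1.0, 1.0)
        cand = float(np.clip(pos[i] + phi * (pos[i] - pos[k]), 0.0, 1.0))
        v = obj(cand)
        if v < val[i]:
            pos[i], val[i] = cand, v
            trials[i] = 0
            if v < best_v:
                best_a, best_v = cand, v
        else:
            trials[i] += 1

    for _ in range(max_iter):
        for i in range(colony):  # employed phase
            try_move(i)
        fitness = 1.0 / (1.0 + val - val.min())
        probs = fitness / fitness.sum()
        for _ in range(colony):  # onlooker phase
            try_move(int(rng.choice(colony, p=probs)))
        worn = np.where(trials > limit)[0]
        for i in worn:  # scout phase
            pos[i] = rng.uniform(0.0, 1.0)
            val[i] = obj(pos[i])
            trials[i] = 0
            if val[i] < best_v:
                best_a, best_v = float(pos[i]), float(val[i])
    return best_a, best_v


def compare_clusters(values_by_comparison: dict, labels_by_comparison: dict) -> ClusterComparison:
    """Two-sided rank-sum tests with BH correction across the family.

    Each entry of ``values_by_comparison`` is a 1-D array with a matching
    label array in ``labels_by_comparison``; exactly two label levels per
    comparison.  The BH adjustment runs across all comparisons supplied
    together (the scenario x statistic family).
    """
    rows = []
    for name, values in values_by_comparison.items():
        v = np.asarray(values, dtype=float)
        lab = np.asarray(labels_by_comparison[name])
        levels = pd.unique(lab)
        if len(levels) != 2:
            raise ValueError(f"comparison {name!r} needs exactly 2 groups, got {len(levels)}")
        a, b = v[lab == levels[0]], v[lab == levels[1]]
        W, p = rank_sum_test(a, b)
        rows.append(
            {
                "comparison": name,
                "group_a": levels[0],
                "group_b": levels[1],
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "W": W,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return ClusterComparison(table)


def build_risk_surface(
    delta_s,
    offset,
    clusters,
    alpha: float | None = None,
    seed: int = 0,
    decreased_only: bool = True,
    objective: str = "l2",
    cell_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell risk surface (B, C, A, cluster).

    ``delta_s`` is future-minus-present suitability, ``offset`` the
    genomic offset, ``clusters`` the per-cell cluster label.  By default
    only cells with decreased suitability (delta_s < 0) are analyzed;
    within those, B = scaled |delta_s| and C = scaled offset, both to
    [0, 0.9].  ``alpha`` is optimized by the bee colony when not given.
    """
    delta_s = np.asarray(delta_s, dtype=float)
    offset = np.asarray(offset, dtype=float)
    clusters = np.asarray(clusters)
    mask = delta_s < 0 if decreased_only else np.ones(delta_s.shape, dtype=bool)
    if not mask.any():
        raise ValueError("no cells to analyze (no suitability decrease)")
    B = scale_to_range(delta_s[mask], absolute=True)
    C = scale_to_range(offset[mask])
    if alpha is None:
        alpha, _ = optimize_alpha(B, C, seed=seed, objective=objective)
    A = genomic_niche_index(B, C, alpha)
    n_zero = int(((B == 0) | (C == 0)).sum())
    if n_zero:
        log.info("risk surface: %d boundary cells with a zero base", n_zero)
    out = (
        cell_meta.loc[mask].reset_index(drop=True).copy()
        if cell_meta is not None
        else pd.DataFrame(index=np.arange(mask.sum()))
    )
    out["B"] = B
    out["C"] = C
    out["A"] = A
    out["alpha"] = alpha
    out["cluster"] = clusters[mask]
    return out


def risk_report(surface: pd.DataFrame) -> dict:
    """Rank cells by the genomic-niche index and flag the riskiest cluster.

    Cells are ranked ascending by ``A`` (smaller index = higher overall
    risk); the cluster with the lowest mean index is flagged highest-risk
    unless all values tie.
    """
    ranked = surface.sort_values("A", kind="mergesort").reset_index(drop=True)
    means = surface.groupby("cluster")["A"].mean()
    if surface["A"].nunique() == 1:
        flag = None
        log.info("risk report: all index values equal, no cluster flagged")
    else:
        flag = means.idxmin()
    return {
        "ranked": ranked,
        "cluster_means": {k: round(float(v), 3) for k, v in means.items()},
        "highest_risk_cluster": flag,
    }
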