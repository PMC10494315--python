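"""Gradient forest: turnover functions and genomic offset.

For every locus, a random-forest regression of site allele frequency on
the environmental + spatial predictors yields an out-of-bag R2 and a set
of split improvements (impurity reductions) located at split thresholds
along each predictor.  Improvements are binned along each predictor's
observed range, standardized by the data density (importance per unit of
predictor density), weighted by the locus R2 (loci with R2 <= 0 carry no
weight), and accumulated into a nondecreasing cumulative-importance
curve per predictor — the turnover function.  Mapping an environment
through these curves gives its position in "genomic composition" space;
the genomic offset of a cell is the Euclidean distance between its
present-day and future positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestRegressor

from .io import EnvTable, SchemaError, log
from .stats import rank_sum_test


class EmptyModelError(ValueError):
    pass


@dataclass
class CumulativeCurve:
    """Nondecreasing cumulative importance along one predictor."""

    x: np.ndarray  # breakpoints (bin edges)
    y: np.ndarray  # cumulative importance at each breakpoint, starts at 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.y) < -1e-12):
            raise ValueError("cumulative curve must be nondecreasing")

    @property
    def total(self) -> float:
        return float(self.y[-1]) if len(self.y) else 0.0

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Monotone linear interpolation; constant beyond the range."""
        return np.interp(values, self.x, self.y, left=0.0, right=self.total)


@dataclass
class GFModel:
    predictors: list[str]
    r2: pd.Series  # per-locus out-of-bag R2
    curves: dict[str, CumulativeCurve]
    raw_importance: pd.DataFrame  # kept loci x predictors, R2-weighted
    overall_importance: pd.Series  # per predictor
    kept_loci: list[str]
    n_trees: int
    corr_threshold: float
    config: dict = field(default_factory=dict)

    def transform(self, env: pd.DataFrame | EnvTable) -> np.ndarray:
        """Map environments into cumulative-importance space.

        Output has one column per model predictor, in model order.
        """
        df = env.data if isinstance(env, EnvTable) else env
        missing = [p for p in self.predictors if p not in df.columns]
        if missing:
            raise SchemaError(f"environment lacks model predictors: {missing}")
        return np.column_stack(
            [self.curves[p].transform(df[p].to_numpy(dtype=float)) for p in self.predictors]
        )


def _tree_split_improvements(tree, n_total: float):
    """(feature, threshold, improvement) for every internal node.

    Improvement is the sample-weighted impurity decrease normalized by
    the total training weight — the quantity behind mean-decrease-in-
    impurity importances.
    """
    t = tree.tree_
    left, right = t.children_left, t.children_right
    internal = np.where(left != -1)[0]
    nn = t.weighted_n_node_samples
    imp = t.impurity
    gain = (
        nn[internal] * imp[internal]
        - nn[left[internal]] * imp[left[internal]]
        - nn[right[internal]] * imp[right[internal]]
    ) / n_total
    return t.feature[internal], t.threshold[internal], np.maximum(gain, 0.0)


def _forest_oob_r2(forest, X, y) -> float:
    """Out-of-bag R2: 1 - OOB MSE / variance of the response."""
    try:
        score = forest.oob_score_
    except AttributeError:
        return float("-inf")
    return float(score) if np.isfinite(score) else float("-inf")


def _density_standardize(hist: np.ndarray, edges: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Divide binned importance by the predictor's data density.

    Density is a Gaussian KDE (Silverman bandwidth) at bin centers, so
    bins in data-sparse regions are up-weighted: importance per unit of
    predictor density.  Total mass is preserved.
    """
    total = hist.sum()
    if total <= 0 or len(np.unique(values)) < 2:
        return hist
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        dens = gaussian_kde(values, bw_method="silverman")(centers)
    except np.linalg.LinAlgError:
        return hist
    dens = np.maximum(dens, 1e-3 * dens.max())
    out = hist / dens
    return out / out.sum() * total


def fit_gradient_forest(
    F: pd.DataFrame,
    X: pd.DataFrame,
    n_trees: int = 500,
    corr_threshold: float = 0.50,
    seed: int = 0,
    n_bins: int = 201,
) -> GFModel:
    """Fit per-locus regression forests and aggregate turnover curves.

    ``F`` is the site x locus allele-frequency table, ``X`` the site-level
    predictors in the same row order.  Constant predictors are dropped
    with a warning.  Trees use variance-reduction splits with
    ``mtry = ceil(p/3)`` and a minimum node size of 5 (reduced for tiny
    site counts); per-locus R2 is out-of-bag.  Split improvements of loci
    with R2 > 0 are pooled with R2 weights, binned into ``n_bins``
    equal-width bins per predictor, density-standardized, and cumulated.
    A predictor's overall importance is the R2-weighted mean of its split
    improvement share, which equals the endpoint of its cumulative curve.
    """
    if F.shape[0] < 4:
        raise ValueError("need at least 4 sites")
    if F.shape[1] < 1:
        raise ValueError("need at least one locus")
    keep_pred = [p for p in X.columns if X[p].nunique() > 1]
    dropped = [p for p in X.columns if p not in keep_pred]
    if dropped:
        log.warning("gradient forest dropped constant predictors: %s", dropped)
    X = X[keep_pred]
    preds = list(X.columns)
    if not preds:
        raise EmptyModelError("no non-constant predictors")
    Xv = X.to_numpy(dtype=float)
    n_sites, p = Xv.shape
    mtry = max(1, int(np.ceil(p / 3)))
    min_leaf = min(5, max(1, n_sites // 3))
    rng = np.random.default_rng(seed)

    r2: dict[str, float] = {}
    locus_splits: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    locus_share: dict[str, dict[str, float]] = {}
    for locus in F.columns:
        y = F[locus].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            r2[locus] = float("-inf")
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mtry,
            min_samples_leaf=min_leaf,
            bootstrap=True,
            oob_score=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(Xv, y)
        r2[locus] = _forest_oob_r2(forest, Xv, y)
        feats_all, thr_all, gain_all = [], [], []
        for est in forest.estimators_:
            f, t, g = _tree_split_improvements(est, n_sites * n_trees)
            feats_all.append(f)
            thr_all.append(t)
            gain_all.append(g)
        feats = np.concatenate(feats_all)
        thr = np.concatenate(thr_all)
        gain = np.concatenate(gain_all)
        total = gain.sum()
        locus_splits[locus] = {}
        locus_share[locus] = {}
        for qi, q in enumerate(preds):
            m = feats == qi
            locus_splits[locus][q] = (thr[m], gain[m])
            locus_share[locus][q] = float(gain[m].sum() / total) if total > 0 else 0.0

    r2_series = pd.Series(r2).reindex(F.columns)
    kept = [l for l in F.columns if np.isfinite(r2_series[l]) and r2_series[l] > 0]
    if not kept:
        raise EmptyModelError("no locus has positive out-of-bag R2")

    raw_importance = pd.DataFrame(
        {q: [r2_series[l] * locus_share[l][q] for l in kept] for q in preds}, index=kept
    )
    overall = raw_importance.mean(axis=0)

    curves: dict[str, CumulativeCurve] = {}
    w_sum = float(r2_series[kept].sum())
    for qi, q in enumerate(preds):
        xv = Xv[:, qi]
        lo, hi = float(xv.min()), float(xv.max())
        edges = np.linspace(lo, hi, n_bins + 1)
        hist = np.zeros(n_bins)
        for locus in kept:
            thr_l, gain_l = locus_splits[locus][q]
            if len(thr_l) == 0:
                continue
            gtot = sum(g.sum() for _, g in locus_splits[locus].values())
            if gtot <= 0:
                continue
            wloc = r2_series[locus] / w_sum
            idx = np.clip(np.searchsorted(edges, thr_l, side="right") - 1, 0, n_bins - 1)
            np.add.at(hist, idx, wloc * gain_l / gtot)
        hist = _density_standardize(hist, edges, xv)
        if hist.sum() > 0:
            hist = hist / hist.sum() * float(overall[q])
        y = np.concatenate([[0.0], np.cumsum(hist)])
        curves[q] = CumulativeCurve(x=edges, y=np.maximum.accumulate(y))

    model = GFModel(
        predictors=preds,
        r2=r2_series,
        curves=curves,
        raw_importance=raw_importance,
        overall_importance=overall,
        kept_loci=kept,
        n_trees=n_trees,
        corr_threshold=corr_threshold,
        config={"mtry": mtry, "min_samples_leaf": min_leaf, "n_bins": n_bins, "seed": seed},
    )
    log.info(
        "gradient forest: %d/%d loci with R2>0; top predictor %s",
        len(kept), F.shape[1], overall.idxmax(),
    )
    return model


def genomic_offset(
    model: GFModel, env_present: EnvTable | pd.DataFrame, env_future: EnvTable | pd.DataFrame
) -> pd.DataFrame:
    """Per-cell Euclidean distance between transformed environments.

    Grids must be cell-aligned and carry every model predictor.  Returns
    a frame with cell metadata and an ``offset`` column (importance
    units; nonnegative, and exactly zero wherever future equals present).
    """
    dfp = env_present.data if isinstance(env_present, EnvTable) else env_present
    dff = env_future.data if isinstance(env_future, EnvTable) else env_future
    if len(dfp) != len(dff):
        raise SchemaError("present and future grids must be cell-aligned")
    tp = model.transform(dfp)
    tf = model.transform(dff)
    off = np.linalg.norm(tp - tf, axis=1)
    out_cols = [c for c in ("cell_id", "lon", "lat", "coast") if c in dfp.columns]
    out = dfp[out_cols].copy() if out_cols else pd.DataFrame(index=dfp.index)
    out["offset"] = off
    return out


def compare_offsets(surface: pd.DataFrame, labels) -> dict:
    """Group summary (means, SDs) plus a rank-sum test handle."""
    labels = np.asarray(labels)
    off = surface["offset"].to_numpy(dtype=float)
    groups = {g: off[labels == g] for g in pd.unique(labels)}
    summary = {
        g: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0, "n": len(v)}
        for g, v in groups.items()
    }
    if len(groups) == 2:
        (ga, va), (gb, vb) = groups.items()
        W, pval = rank_sum_test(va, vb)
        summary["test"] = {"groups": (ga, gb), "W": W, "p": pval}
    return summary
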