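"""Presence-background habitat suitability modelling (MaxEnt-style).

The model is the penalized-logistic equivalent of MaxEnt: presences are
contrasted with background cells over feature expansions of the
environmental predictors (linear, quadratic, pairwise product, hinge),
with an L1 penalty scaled by a regularization multiplier, and a cloglog
output transform.  Tuning fits a grid of feature-class sets x
multipliers under 5-fold cross-validation and ranks candidates by mean
omission rate at the p10 threshold, breaking ties by validation AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .io import EnvTable, OccurrenceSet, log
from .ordination import haversine_matrix

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")
DEFAULT_FEATURE_SETS = (
    ("linear",),
    ("linear", "quadratic"),
    ("linear", "quadratic", "product"),
    ("linear", "quadratic", "product", "hinge"),
)
DEFAULT_MULTIPLIERS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

# Total weight assigned to the background sample in the weighted logistic
# fit; constant so that duplicating background points leaves the
# likelihood, and hence the coefficients, unchanged.
_BG_WEIGHT = 100.0


class FitError(RuntimeError):
    pass


@dataclass
class FeatureMap:
    """Feature expansion shared between fitting and prediction."""

    predictors: list[str]
    features: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    hinge_knots: dict[str, np.ndarray] = field(default_factory=dict)
    hinge_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def build(cls, df: pd.DataFrame, predictors, features, n_hinge: int = 30):
        X = df[list(predictors)].to_numpy(dtype=float)
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        knots, ranges = {}, {}
        if "hinge" in features:
            for j, p in enumerate(predictors):
                # interior quantile knots, split between forward and reverse hinges
                qs = np.linspace(0.05, 0.95, n_hinge // 2)
                knots[p] = np.quantile(X[:, j], qs)
                ranges[p] = (float(X[:, j].min()), float(X[:, j].max()))
        return cls(list(predictors), tuple(features), center, scale, knots, ranges)

    def design(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.predictors].to_numpy(dtype=float)
        Z = (X - self.center) / self.scale
        cols = [Z]
        if "quadratic" in self.features:
            cols.append(Z**2)
        if "product" in self.features:
            p = Z.shape[1]
            cols.extend(Z[:, [i]] * Z[:, [j]] for i in range(p) for j in range(i + 1, p))
        if "hinge" in self.features:
            for j, name in enumerate(self.predictors):
                raw = X[:, j]
                lo, hi = self.hinge_range[name]
                rng = hi - lo if hi > lo else 1.0
                for k in self.hinge_knots[name]:
                    cols.append(np.maximum(0.0, (raw - k))[:, None] / rng)
                    cols.append(np.maximum(0.0, (k - raw))[:, None] / rng)
        return np.column_stack(cols)


@dataclass
class SuitabilityModel:
    feature_map: FeatureMap
    reg_multiplier: float
    coef: np.ndarray
    intercept: float
    train_presence_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def features(self) -> tuple[str, ...]:
        return self.feature_map.features

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.feature_map.design(df) @ self.coef + self.intercept

    def predict(self, env: pd.DataFrame | EnvTable) -> np.ndarray:
        """Cloglog suitability in (0, 1)."""
        df = env.data if isinstance(env, EnvTable) else env
        eta = self.linear_predictor(df)
        s = 1.0 - np.exp(-np.exp(eta))
        return np.clip(s, 1e-12, 1.0 - 1e-12)


@dataclass
class EvalReport:
    per_fold: pd.DataFrame  # fold, auc, tss, boyce, omission
    auc: float
    tss: float
    boyce: float
    omission: float

    def __post_init__(self) -> None:
        if not (0 <= self.auc <= 1):
            raise ValueError("AUC out of range")
        if not (-1 <= self.tss <= 1):
            raise ValueError("TSS out of range")


# ---------------------------------------------------------------------------
# occurrence preparation


def prepare_occurrences(
    occ: OccurrenceSet,
    grid: EnvTable,
    buffer_km: float = 1000.0,
    n_background: int = 10000,
    seed: int = 0,
):
    """Thin presences to one per grid cell and sample buffered background.

    Each record maps to its nearest grid cell; the first record seen in a
    cell is kept (duplicates logged).  The study extent is the union of
    ``buffer_km`` haversine buffers around presence cells; background
    cells are sampled uniformly over the extent without replacement, or
    with replacement (logged) when the extent is smaller than
    ``n_background``.  Returns ``(presences, background)`` as grid-row
    DataFrames.
    """
    rng = np.random.default_rng(seed)
    gdf = grid.data.reset_index(drop=True)
    glon = gdf["lon"].to_numpy(float)
    glat = gdf["lat"].to_numpy(float)
    rec = occ.records
    cell_idx: list[int] = []
    seen: set[int] = set()
    n_dup = 0
    for lon, lat in zip(rec["lon"].to_numpy(float), rec["lat"].to_numpy(float)):
        # nearest cell in degree space (regular grid)
        i = int(np.argmin((glon - lon) ** 2 + (glat - lat) ** 2))
        if i in seen:
            n_dup += 1
            continue
        seen.add(i)
        cell_idx.append(i)
    if n_dup:
        log.info("occurrence thinning: dropped %d duplicate-cell records", n_dup)
    presences = gdf.iloc[cell_idx].copy()
    if "cluster" in rec.columns and len(cell_idx):
        # carry the cluster label of the first record per kept cell
        labels = []
        used = set()
        for lon, lat, cl in zip(rec["lon"], rec["lat"], rec["cluster"]):
            i = int(np.argmin((glon - lon) ** 2 + (glat - lat) ** 2))
            if i in used:
                continue
            used.add(i)
            labels.append(cl)
        presences["cluster"] = labels

    if buffer_km <= 0:
        extent = np.zeros(len(gdf), dtype=bool)
        extent[list(seen)] = True
    else:
        D = haversine_matrix(
            np.concatenate([glon, presences["lon"].to_numpy(float)]),
            np.concatenate([glat, presences["lat"].to_numpy(float)]),
        )[: len(gdf), len(gdf):]
        extent = (D <= buffer_km).any(axis=1)
    extent_idx = np.flatnonzero(extent)
    replace = len(extent_idx) < n_background
    if replace:
        log.info(
            "background: extent has %d cells < %d requested, sampling with replacement",
            len(extent_idx), n_background,
        )
    bg_idx = rng.choice(extent_idx, size=n_background, replace=replace)
    background = gdf.iloc[bg_idx].copy()
    return presences, background


# ---------------------------------------------------------------------------
# fitting


def maxent_fit(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    predictors: list[str],
    features: tuple[str, ...] = ("linear", "quadratic", "hinge"),
    reg_multiplier: float = 1.0,
    n_hinge: int = 30,
) -> SuitabilityModel:
    """Fit the penalized presence-background logistic model.

    Background points carry a constant total weight, so duplicating them
    changes nothing; the L1 penalty strength is proportional to
    ``reg_multiplier``.
    """
    if len(presences) < 2:
        raise FitError("need at least 2 presences")
    # feature scaling and hinge knots come from the background sample (the
    # available environment), so exact duplication of background points
    # leaves the feature map unchanged
    fmap = FeatureMap.build(background, predictors, features, n_hinge=n_hinge)
    Xp = fmap.design(presences)
    Xb = fmap.design(background)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    w = np.concatenate(
        [np.ones(len(Xp)), np.full(len(Xb), _BG_WEIGHT / len(Xb))]
    )
    # L1 penalty proportional to the regularization multiplier per unit of
    # total sample weight (weight-preserving duplication changes nothing),
    # and growing with the square root of the feature-space size so that
    # large hinge expansions are penalized more heavily
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=float(w.sum()) / (max(reg_multiplier, 1e-6) * np.sqrt(X.shape[1])),
        solver="liblinear",
        max_iter=50000,
        tol=1e-9,
        random_state=0,
    )
    clf.fit(X, y, sample_weight=w)
    if not np.isfinite(clf.coef_).all():
        raise FitError("non-finite coefficients; increase the regularization multiplier")
    model = SuitabilityModel(
        feature_map=fmap,
        reg_multiplier=reg_multiplier,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
    )
    model.train_presence_scores = model.predict(presences)
    return model


# ---------------------------------------------------------------------------
# evaluation metrics (standalone, oracle-checkable)


def auc_score(presence_scores, background_scores) -> float:
    """Rank AUC of presences vs background (Mann-Whitney statistic)."""
    y = np.concatenate([np.ones(len(presence_scores)), np.zeros(len(background_scores))])
    s = np.concatenate([presence_scores, background_scores])
    return float(roc_auc_score(y, s))


def tss_score(presence_scores, background_scores) -> tuple[float, float]:
    """Max over thresholds of sensitivity + specificity - 1, with argmax."""
    y = np.concatenate([np.ones(len(presence_scores)), np.zeros(len(background_scores))])
    s = np.concatenate([presence_scores, background_scores])
    fpr, tpr, thr = roc_curve(y, s)
    i = int(np.argmax(tpr - fpr))
    return float(tpr[i] - fpr[i]), float(thr[i])


def boyce_index(
    presence_scores, background_scores, n_windows: int = 101, width: float = 0.1
) -> float:
    """Continuous Boyce index over overlapping suitability windows.

    Spearman correlation between the window midpoint and the
    predicted-to-expected presence ratio, over ``n_windows`` windows of
    ``width`` (on the pooled suitability range); windows with no
    background mass are skipped.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    lo = min(p.min(), b.min())
    hi = max(p.max(), b.max())
    span = hi - lo if hi > lo else 1.0
    w = width * span
    starts = np.linspace(lo, hi - w, n_windows)
    mids, ratios = [], []
    for s0 in starts:
        s1 = s0 + w
        fp = ((p >= s0) & (p <= s1)).mean()
        fb = ((b >= s0) & (b <= s1)).mean()
        if fb <= 0:
            continue
        mids.append(s0 + w / 2)
        ratios.append(fp / fb)
    if len(mids) < 3:
        return float("nan")
    rho = spearmanr(mids, ratios).statistic
    return float(rho)


def p10_threshold(presence_scores) -> float:
    """Suitability at the 10th percentile of training presence scores."""
    return float(np.quantile(np.asarray(presence_scores, dtype=float), 0.10))


def omission_rate(presence_scores, threshold: float) -> float:
    return float((np.asarray(presence_scores, dtype=float) < threshold).mean())


def evaluate(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    predictors: list[str],
    features=("linear", "quadratic", "hinge"),
    reg_multiplier: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """5-fold cross-validation of one candidate parameterization.

    Presences are partitioned into folds (background is shared); each
    fold's model is scored on its held-out presences against the full
    background: AUC, TSS, Boyce, and omission at the p10 threshold of the
    training presences.
    """
    rng = np.random.default_rng(seed)
    n = len(presences)
    folds = min(folds, n)
    assign = rng.permutation(n) % folds
    rows = []
    for f in range(folds):
        train = presences.iloc[assign != f]
        test = presences.iloc[assign == f]
        if len(train) < 2 or len(test) < 1:
            continue
        model = maxent_fit(train, background, predictors, features, reg_multiplier)
        s_test = model.predict(test)
        s_bg = model.predict(background)
        thr = p10_threshold(model.train_presence_scores)
        rows.append(
            {
                "fold": f,
                "auc": auc_score(s_test, s_bg),
                "tss": tss_score(s_test, s_bg)[0],
                "boyce": boyce_index(s_test, s_bg),
                "omission": omission_rate(s_test, thr),
            }
        )
    per_fold = pd.DataFrame(rows)
    return EvalReport(
        per_fold,
        auc=float(per_fold["auc"].mean()),
        tss=float(per_fold["tss"].mean()),
        boyce=float(np.nanmean(per_fold["boyce"])),
        omission=float(per_fold["omission"].mean()),
    )


def tune_select(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    predictors: list[str],
    feature_sets=DEFAULT_FEATURE_SETS,
    multipliers=DEFAULT_MULTIPLIERS,
    folds: int = 5,
    seed: int = 0,
):
    """Tune over the feature-set x multiplier grid (default 4 x 8 = 32).

    Candidates are ranked by lowest mean cross-validated omission at the
    p10 threshold, ties broken by highest validation AUC, then by grid
    order (logged).  Returns ``(best_model, leaderboard)`` with the best
    candidate refitted on all presences.
    """
    rows = []
    for fi, features in enumerate(feature_sets):
        for mi, mult in enumerate(multipliers):
            rep = evaluate(presences, background, predictors, features, mult, folds, seed)
            rows.append(
                {
                    "features": "+".join(features),
                    "reg_multiplier": mult,
                    "omission": rep.omission,
                    "auc": rep.auc,
                    "tss": rep.tss,
                    "boyce": rep.boyce,
                    "order": fi * len(multipliers) + mi,
                }
            )
    board = pd.DataFrame(rows).sort_values(
        ["omission", "auc", "order"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    if len(board) > 1 and board.loc[0, ["omission", "auc"]].equals(board.loc[1, ["omission", "auc"]]):
        log.info("tune_select: tie at the top of the leaderboard, keeping grid order")
    best = board.iloc[0]
    features = tuple(best["features"].split("+"))
    model = maxent_fit(presences, background, predictors, features, float(best["reg_multiplier"]))
    return model, board


# ---------------------------------------------------------------------------
# thresholds and change surfaces


def _cell_areas(lat) -> np.ndarray:
    """Relative cell areas on a regular lon/lat grid: cos(latitude)."""
    return np.cos(np.radians(np.asarray(lat, dtype=float)))


def binarize_and_change(
    model: SuitabilityModel,
    grid_present: EnvTable,
    grid_future: EnvTable,
    background: pd.DataFrame | None = None,
) -> dict:
    """Suitability surfaces, binary maps at p10/maxTSS, delta-S and range change.

    Range-size change is ``(area_future - area_present)/area_present x
    100`` with cos(latitude)-weighted cell areas, reported for both
    thresholds.  Delta-S is future minus present suitability, in [-1, 1].
    """
    dfp = grid_present.data
    s_present = model.predict(grid_present)
    s_future = model.predict(grid_future)
    thr_p10 = p10_threshold(model.train_presence_scores)
    bg = background if background is not None else dfp
    tss, thr_tss = tss_score(model.train_presence_scores, model.predict(bg))
    areas = _cell_areas(dfp["lat"]) if "lat" in dfp else np.ones(len(dfp))
    out = {
        "suitability_present": s_present,
        "suitability_future": s_future,
        "delta_s": s_future - s_present,
        "thresholds": {"p10": thr_p10, "maxTSS": thr_tss},
        "range_change_pct": {},
        "binary": {},
    }
    for name, thr in out["thresholds"].items():
        bp = s_present >= thr
        bf = s_future >= thr
        ap = float((areas * bp).sum())
        af = float((areas * bf).sum())
        out["binary"][name] = {"present": bp, "future": bf}
        out["range_change_pct"][name] = (af - ap) / ap * 100.0 if ap > 0 else float("nan")
    return out


def range_change_pct(binary_present, binary_future, lat=None) -> float:
    """Range-size change in percent from two binary maps."""
    bp = np.asarray(binary_present, dtype=bool)
    bf = np.asarray(binary_future, dtype=bool)
    areas = _cell_areas(lat) if lat is not None else np.ones(bp.shape)
    ap = float((areas * bp).sum())
    af = float((areas * bf).sum())
    return (af - ap) / ap * 100.0 if ap > 0 else float("nan")
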