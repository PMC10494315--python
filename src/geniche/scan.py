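"""Genome scans for putatively adaptive SNPs.

Two complementary detectors, each correcting for population structure:

* a PCA-outlier scan: regress each scaled locus on the leading K principal
  components of the genotype matrix, form the Mahalanobis distance of the
  K z-score vector, recalibrate with the genomic inflation factor, and
  convert to chi-square p-values;
* an environmental-association scan with latent factors: per environmental
  PC, fit genotype = env effect + K latent factors by alternating least
  squares, recalibrate z-scores by genomic inflation, and flag loci with
  |z| above a cutoff and a Benjamini-Hochberg q-value below the FDR level.

Loci flagged by at least one detector form the putatively adaptive set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, log
from .stats import bh_adjust


class DimensionError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, n_iter: int):
        super().__init__(msg)
        self.n_iter = n_iter


class EmptyResultError(ValueError):
    pass


@dataclass
class ScanResult:
    """Per-locus statistics of one scan plus the flagged adaptive set."""

    table: pd.DataFrame  # locus, stat, p, q, flagged
    K: int
    inflation: float
    method: str
    adaptive: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        q = self.table["q"].to_numpy()
        if ((q < 0) | (q > 1)).any():
            raise ValueError("q-values must lie in [0, 1]")
        if not self.adaptive <= set(self.table["locus"]):
            raise ValueError("adaptive set must be a subset of tested loci")


def filter_maf(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop loci whose minor allele frequency is at or below ``maf_min``.

    MAF is computed over non-missing calls only.
    """
    alt = np.nansum(gm.dosage, axis=0)
    n_called = 2.0 * (~np.isnan(gm.dosage)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(alt, n_called - alt) / n_called
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep = maf > maf_min
    n_drop = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError("all loci removed by the MAF filter")
    log.info("MAF filter: removed %d of %d loci", n_drop, gm.n_loci)
    return gm.subset_loci(keep)


def _scaled_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Impute, center, and scale dosages by sqrt(p(1-p)) per locus."""
    G = gm.imputed()
    p = G.mean(axis=0) / 2.0
    sd = np.sqrt(p * (1.0 - p))
    sd[sd == 0] = 1.0
    return (G - 2.0 * p) / sd


def pcadapt_scan(gm: GenotypeMatrix, K: int = 5, q_max: float = 0.05) -> ScanResult:
    """PCA-outlier scan with Mahalanobis distance and inflation correction.

    Each scaled locus is regressed on the leading ``K`` PC score vectors;
    the K-vector of regression z-scores is summarized by its Mahalanobis
    distance under the empirical covariance, divided by the genomic
    inflation factor, and referred to a chi-square with K degrees of
    freedom.  Loci with BH q-value below ``q_max`` are flagged.
    """
    n, m = gm.dosage.shape
    if K >= min(n, m):
        raise DimensionError(f"K={K} must be below min(n_individuals, n_loci)={min(n, m)}")
    Z = _scaled_matrix(gm)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    if K >= np.sum(s > 1e-10 * s[0]):
        raise DimensionError(f"K={K} is not below the matrix rank")
    Uk = U[:, :K]  # orthonormal design
    B = Uk.T @ Z  # (K, m) regression coefficients
    resid = Z - Uk @ B
    dof = max(n - K - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    zscores = B / sigma  # se of each coef is sigma (orthonormal design)

    cov = np.cov(zscores)
    cov_inv = np.linalg.pinv(np.atleast_2d(cov))
    d2 = np.einsum("ij,ik,kj->j", zscores, cov_inv, zscores)
    lam = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    pvals = stats.chi2.sf(d2 / lam, K)
    qvals = bh_adjust(pvals)
    flagged = qvals < q_max
    table = pd.DataFrame(
        {"locus": gm.locus_ids, "stat": d2, "p": pvals, "q": qvals, "flagged": flagged}
    )
    return ScanResult(table, K, lam, "pcadapt", set(table.loc[flagged, "locus"]))


def env_pca_retain(env: pd.DataFrame, predictors: list[str], cum_var: float = 0.90):
    """PCA of standardized predictors; retain leading PCs past ``cum_var``.

    Returns ``(scores, loadings, explained_ratio)`` where scores has the
    smallest leading set of PCs whose cumulative explained variance
    exceeds ``cum_var``.
    """
    X = env[predictors].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(ratio), cum_var) + 1)
    n_keep = min(n_keep, len(ratio))
    scores = pd.DataFrame(
        U[:, :n_keep] * s[:n_keep], columns=[f"envPC{i + 1}" for i in range(n_keep)]
    )
    loadings = pd.DataFrame(Vt[:n_keep].T, index=predictors, columns=scores.columns)
    return scores, loadings, ratio


def _lfmm_fit(Y, x, K, rng, max_iter=200, tol=1e-6, ridge=1e-3):
    """Alternating least squares for Y = x b' + U V' + E; returns b, se."""
    n, m = Y.shape
    x = x.reshape(-1, 1)
    if K == 0:
        D = x
    else:
        U = rng.standard_normal((n, K)) * 0.1
        D = np.column_stack([x, U])
    # block coordinate descent on ||Y - x b' - U V'||^2 + ridge ||U||^2:
    # each block step is an exact minimizer, so the objective is monotone
    prev_obj = None
    for n_iter in range(1, max_iter + 1):
        C, *_ = np.linalg.lstsq(D, Y, rcond=None)
        b = C[0]
        if K == 0:
            break
        V = C[1:].T  # (m, K)
        R = Y - x @ b.reshape(1, -1)
        VtV = V.T @ V + ridge * np.eye(K)
        U = R @ V @ np.linalg.inv(VtV)
        D = np.column_stack([x, U])
        obj = float(((Y - x @ b.reshape(1, -1) - U @ V.T) ** 2).sum()) + ridge * float(
            (U**2).sum()
        )
        if prev_obj is not None and abs(prev_obj - obj) <= tol * max(prev_obj, 1e-12):
            break
        prev_obj = obj
    else:
        raise ConvergenceError(f"LFMM ALS did not converge in {max_iter} iterations", max_iter)
    # z-scores from the final joint regression
    C, *_ = np.linalg.lstsq(D, Y, rcond=None)
    b = C[0]
    resid = Y - D @ C
    dof = max(n - D.shape[1] - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    DtD_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[0, 0], 1e-300))
    return b / se


def lfmm_scan(
    gm: GenotypeMatrix,
    env_pcs: pd.DataFrame,
    K: int = 5,
    replicates: int = 5,
    z_min: float = 2.0,
    q_max: float = 0.05,
    seed: int = 0,
    max_iter: int = 200,
) -> ScanResult:
    """Latent-factor association scan across environmental PCs.

    ``env_pcs`` must be row-aligned with individuals (site-level values
    broadcast beforehand).  For each environmental PC, ``replicates``
    restarts of the alternating-least-squares fit differ only in the
    random initialization of the latent factors; the per-locus z-score is
    the median over replicates, recalibrated by the genomic inflation
    factor.  A locus is flagged if, for any PC, |z| > ``z_min`` and its
    within-PC BH q-value is below ``q_max``; the union over PCs is
    returned.  Per-locus entries in the result table are taken from the
    PC giving the smallest p.
    """
    if len(env_pcs) != gm.n_individuals:
        raise ValueError("env_pcs must have one row per individual")
    Z = _scaled_matrix(gm)
    rng = np.random.default_rng(seed)
    m = gm.n_loci
    best_p = np.ones(m)
    best_z = np.zeros(m)
    best_q = np.ones(m)
    flagged = np.zeros(m, dtype=bool)
    lams = []
    for col in env_pcs.columns:
        x = env_pcs[col].to_numpy(dtype=float)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        zs = np.median(
            [_lfmm_fit(Z, x, K, rng, max_iter=max_iter) for _ in range(replicates)], axis=0
        )
        lam = float(np.median(zs**2) / stats.chi2.ppf(0.5, 1))
        lam = max(lam, 1e-12)
        lams.append(lam)
        z_cal = zs / np.sqrt(lam)
        p = 2.0 * stats.norm.sf(np.abs(z_cal))
        q = bh_adjust(p)
        flagged |= (np.abs(z_cal) > z_min) & (q < q_max)
        better = p < best_p
        best_p[better] = p[better]
        best_z[better] = z_cal[better]
        best_q[better] = q[better]
    table = pd.DataFrame(
        {"locus": gm.locus_ids, "stat": best_z**2, "p": best_p, "q": best_q, "flagged": flagged}
    )
    return ScanResult(
        table, K, float(np.median(lams)), "lfmm", set(table.loc[flagged, "locus"])
    )


def union_adaptive(a: ScanResult, b: ScanResult) -> tuple[set[str], dict]:
    """Loci flagged by at least one scan, with overlap bookkeeping."""
    union = a.adaptive | b.adaptive
    report = {
        "a_only": len(a.adaptive - b.adaptive),
        "b_only": len(b.adaptive - a.adaptive),
        "intersection": len(a.adaptive & b.adaptive),
        "union": len(union),
    }
    log.info(
        "adaptive union: %d (%s) + %d (%s) with overlap %d -> %d",
        len(a.adaptive), a.method, len(b.adaptive), b.method,
        report["intersection"], report["union"],
    )
    return union, report


def broadcast_env_to_individuals(gm: GenotypeMatrix, site_table: pd.DataFrame, columns) -> pd.DataFrame:
    """Expand per-site values to one row per individual, order-aligned."""
    lut = site_table.set_index("site")
    return pd.DataFrame(
        {c: [lut.loc[s, c] for s in gm.site_labels] for c in columns}
    )
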