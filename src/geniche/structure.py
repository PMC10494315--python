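"""Population structure from adaptive SNPs: admixture and genotype PCA.

The admixture model treats each genotype call (0/1/2 copies of the ALT
allele) as a categorical draw from a mixture of K ancestral components:
``P(g_il = c) = sum_k Q_ik G_klc`` with per-individual ancestry
proportions Q on the simplex and ancestral genotype-category frequencies
G.  It is fitted by expectation-maximization with a small Dirichlet
prior, which is guaranteed not to decrease the (penalized) training
likelihood at any update.  Model choice follows the masked cross-entropy
rule: a fraction of genotype entries is held out per replicate, and the K
minimizing the replicate-mean held-out cross-entropy wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, log


class DimensionError(ValueError):
    pass


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # n_individuals x K
    G: np.ndarray  # K x n_loci x 3 ancestral genotype-category frequencies
    cross_entropy: pd.DataFrame  # columns K, replicate, cross_entropy
    chosen_K: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-12).any() or (self.G < -1e-12).any():
            raise ValueError("Q and G must be nonnegative")
        if not np.isfinite(self.cross_entropy["cross_entropy"]).all():
            raise ValueError("cross-entropy must be finite")


def _one_hot_codes(gm: GenotypeMatrix) -> np.ndarray:
    """Genotypes as integer categories 0/1/2, -1 where missing."""
    d = gm.dosage
    codes = np.where(np.isnan(d), -1, d).astype(int)
    return codes


def _em_admixture(codes, K, rng, mask, n_iter=200, tol=1e-6, alpha=0.1):
    """MAP EM for the categorical admixture mixture on unmasked cells.

    ``mask`` marks held-out cells (excluded from training along with
    missing calls).  Returns (Q, G, training cross-entropy trace).
    """
    n, m = codes.shape
    obs = (codes >= 0) & ~mask
    Q = rng.dirichlet(np.ones(K), size=n)
    G = rng.dirichlet(np.ones(3), size=(K, m))
    ii, ll = np.where(obs)
    cc = codes[ii, ll]
    trace = []
    prev_ll = -np.inf
    for _ in range(n_iter):
        # E-step: responsibilities for each observed cell
        w = Q[ii] * G[:, ll, cc].T  # (n_obs, K)
        tot = w.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1e-300
        r = w / tot
        ll_val = float(np.log(tot).mean())
        trace.append(-ll_val)
        # M-step with Dirichlet(1 + alpha) smoothing
        Qn = np.zeros((n, K))
        np.add.at(Qn, ii, r)
        Q = (Qn + alpha) / (Qn.sum(axis=1, keepdims=True) + alpha * K)
        Gn = np.zeros((K, m, 3))
        np.add.at(Gn.transpose(1, 2, 0), (ll, cc), r)
        G = (Gn + alpha) / (Gn.sum(axis=2, keepdims=True) + 3 * alpha)
        if abs(ll_val - prev_ll) < tol:
            break
        prev_ll = ll_val
    return Q, G, trace


def _cross_entropy(codes, cells, Q, G) -> float:
    """Mean negative log predicted probability of held-out genotype cells."""
    ii, ll = cells
    cc = codes[ii, ll]
    p = np.einsum("ik,ik->i", Q[ii], G[:, ll, cc].T)
    return float(-np.log(np.maximum(p, 1e-300)).mean())


def snmf_admixture(
    gm: GenotypeMatrix,
    K_range=range(1, 9),
    replicates: int = 10,
    mask_frac: float = 0.05,
    seed: int = 0,
    n_iter: int = 200,
) -> AdmixtureResult:
    """Admixture estimation with masked-cross-entropy model choice.

    For each K and replicate, ``mask_frac`` of the observed genotype cells
    is masked, the EM fit runs on the rest, and the cross-entropy of the
    masked cells under the fitted model is recorded.  The chosen K
    minimizes the replicate-mean cross-entropy; the returned Q/G come from
    the best replicate at that K.
    """
    codes = _one_hot_codes(gm)
    n, m = codes.shape
    K_range = list(K_range)
    if max(K_range) > n:
        raise DimensionError("K cannot exceed the number of individuals")
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for rep in range(replicates):
        mask = (rng.random(codes.shape) < mask_frac) & (codes >= 0)
        held = np.where(mask)
        if held[0].size == 0:
            mask = np.zeros_like(mask)
            held = np.where(codes >= 0)
        for K in K_range:
            Q, G, trace = _em_admixture(codes, K, rng, mask, n_iter=n_iter)
            ce = _cross_entropy(codes, held, Q, G)
            rows.append({"K": K, "replicate": rep, "cross_entropy": ce,
                         "train_ce_initial": trace[0], "train_ce_final": trace[-1]})
            fits[(K, rep)] = (Q, G)
    ce_table = pd.DataFrame(rows)
    means = ce_table.groupby("K")["cross_entropy"].mean()
    chosen_K = int(means.idxmin())
    best_rep = int(
        ce_table[ce_table["K"] == chosen_K]
        .sort_values(["cross_entropy", "replicate"])["replicate"].iloc[0]
    )
    Q, G = fits[(chosen_K, best_rep)]
    log.info("admixture: chose K=%d (mean cross-entropy %.4f)", chosen_K, means[chosen_K])
    return AdmixtureResult(Q, G, ce_table, chosen_K)


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10):
    """PCA of the mean-imputed, centered genotype matrix.

    Returns ``(scores, explained_ratio)``.
    """
    G = gm.imputed()
    Gc = G - G.mean(axis=0)
    U, s, _ = np.linalg.svd(Gc, full_matrices=False)
    var = s**2
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        columns=[f"PC{i + 1}" for i in range(k)],
        index=gm.individual_ids,
    )
    return scores, var / var.sum()


def assign_clusters(Q: np.ndarray, gm: GenotypeMatrix) -> np.ndarray:
    """Label each individual north/south from its dominant admixture component.

    Individuals go to their argmax component (ties broken toward the
    lowest index and logged); each component is then mapped to a
    geographic label by the mean latitude of its members' sites, the
    higher-latitude component becoming "north".  With one component all
    individuals share one label ("north").
    """
    comp = np.argmax(Q, axis=1)
    ties = np.sum(np.isclose(Q, Q.max(axis=1, keepdims=True)), axis=1) > 1
    if ties.any():
        log.info("assign_clusters: %d argmax ties broken to lowest index", int(ties.sum()))
    lat_by_site = dict(zip(gm.site_coords["site"], gm.site_coords["lat"]))
    ind_lat = np.array([lat_by_site[s] for s in gm.site_labels], dtype=float)
    K = Q.shape[1]
    comp_lat = np.array(
        [ind_lat[comp == k].mean() if (comp == k).any() else -np.inf for k in range(K)]
    )
    order = np.argsort(-comp_lat)  # highest mean latitude first
    name = {}
    for rank, k in enumerate(order):
        name[k] = "north" if rank == 0 else ("south" if rank == 1 else f"cluster{rank + 1}")
    return np.array([name[k] for k in comp], dtype=object)
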