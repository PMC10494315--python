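import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import brute_force_bh
from geniche import scan, synthdata
from geniche.io import GenotypeMatrix
from geniche.stats import bh_adjust


def make_gm(dosage, sites=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        dosage=dosage,
        individual_ids=[f"i{k}" for k in range(n)],
        locus_ids=[f"L{k}" for k in range(m)],
        site_labels=np.asarray(sites if sites is not None else ["s0"] * n, dtype=object),
    )


def env_pcs_for(ds, gm):
    pcs, _, _ = scan.env_pca_retain(ds.env_present.data, synthdata.PREDICTORS)
    pcs["site"] = ds.env_present.data["site"].to_numpy()
    return scan.broadcast_env_to_individuals(
        gm, pcs, [c for c in pcs.columns if c != "site"]
    )


class TestMAF:
    def test_borderline_locus_kept(self):
        gm = make_gm([[0], [0], [0], [1]])  # MAF 0.125
        assert scan.filter_maf(gm, 0.05).n_loci == 1

    def test_monomorphic_removed(self):
        gm = make_gm([[0, 1], [0, 1], [0, 1], [0, 1]])
        out = scan.filter_maf(gm, 0.05)
        assert out.locus_ids == ["L1"]

    def test_hand_enumerated_frequencies(self):
        # per-locus ALT counts over 10 individuals: MAF = count/20 or 1-..
        counts = [0, 1, 2, 3, 20, 19, 10, 4, 5, 6]
        dosage = np.zeros((10, 10))
        for j, c in enumerate(counts):
            full, rem = divmod(c, 2)
            dosage[:full, j] = 2
            if rem:
                dosage[full, j] = 1
        gm = make_gm(dosage)
        kept = scan.filter_maf(gm, 0.05)
        expected = sum(1 for c in counts if min(c, 20 - c) / 20 > 0.05)
        assert kept.n_loci == expected

    def test_all_removed_is_error(self):
        gm = make_gm(np.zeros((4, 3)))
        with pytest.raises(scan.EmptyResultError):
            scan.filter_maf(gm)


class TestPCAdapt:
    def test_null_calibration(self, null_ds):
        gm = scan.filter_maf(null_ds.genotypes)
        res = scan.pcadapt_scan(gm, K=5)
        assert 0.8 <= res.inflation <= 1.25
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_ranking_invariant_to_individual_duplication(self, clinal_ds):
        gm = scan.filter_maf(clinal_ds.genotypes.subset_loci(np.arange(100)), 0.05)
        dup = GenotypeMatrix(
            dosage=np.vstack([gm.dosage, gm.dosage]),
            individual_ids=[f"a{k}" for k in range(2 * gm.n_individuals)],
            locus_ids=gm.locus_ids,
            site_labels=np.concatenate([gm.site_labels, gm.site_labels]),
        )
        r1 = scan.pcadapt_scan(gm, K=3)
        r2 = scan.pcadapt_scan(dup, K=3)
        assert (
            r1.table.sort_values("p")["locus"].tolist()
            == r2.table.sort_values("p")["locus"].tolist()
        )

    def test_recall_beats_random_draw(self, clinal_ds):
        gm = scan.filter_maf(clinal_ds.genotypes)
        res = scan.pcadapt_scan(gm, K=3)
        truth = set(clinal_ds.truth["adaptive_loci"]) & set(gm.locus_ids)
        recall = len(res.adaptive & truth) / len(truth)
        rng = np.random.default_rng(0)
        loci = np.array(gm.locus_ids)
        draws = [
            len(set(rng.choice(loci, size=len(res.adaptive), replace=False)) & truth)
            / len(truth)
            for _ in range(999)
        ]
        p = (1 + sum(d >= recall for d in draws)) / 1000
        assert p < 0.01

    def test_k_at_rank_is_dimension_error(self):
        gm = make_gm(np.random.default_rng(0).integers(0, 3, (5, 50)))
        with pytest.raises(scan.DimensionError):
            scan.pcadapt_scan(gm, K=5)

    def test_locus_order_invariance(self, clinal_ds):
        gm = scan.filter_maf(clinal_ds.genotypes.subset_loci(np.arange(80)))
        perm = np.random.default_rng(3).permutation(gm.n_loci)
        r1 = scan.pcadapt_scan(gm, K=3)
        r2 = scan.pcadapt_scan(gm.subset_loci(perm), K=3)
        t1 = r1.table.set_index("locus")["p"]
        t2 = r2.table.set_index("locus")["p"]
        np.testing.assert_allclose(t1[t2.index], t2, rtol=1e-8)


class TestEnvPCA:
    def test_perfectly_correlated_predictors_one_pc(self):
        x = np.linspace(-1, 1, 10)
        env = pd.DataFrame({"a": x, "b": 2 * x})
        scores, _, ratio = scan.env_pca_retain(env, ["a", "b"], 0.90)
        assert scores.shape[1] == 1
        assert ratio[0] > 0.999999

    def test_isotropic_needs_all_pcs(self):
        # orthogonal design: each PC explains exactly 25%
        H = np.array(
            [[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]], dtype=float
        )
        X = np.vstack([H, -H])
        env = pd.DataFrame(X, columns=list("abcd"))
        scores, _, ratio = scan.env_pca_retain(env, list("abcd"), 0.90)
        np.testing.assert_allclose(ratio, 0.25)
        assert scores.shape[1] == 4

    def test_retention_arithmetic(self):
        # eigenvalue shares (0.5, 0.3, 0.15, 0.05) -> 3 PCs pass 0.90
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(400, 4)))
        X = Q * np.sqrt(np.array([0.5, 0.3, 0.15, 0.05]))
        env = pd.DataFrame(X, columns=list("abcd"))
        # bypass re-standardization distortion by feeding orthogonal scores
        U, s, Vt = np.linalg.svd(X - X.mean(0), full_matrices=False)
        ratio = s**2 / (s**2).sum()
        n_keep = int(np.searchsorted(np.cumsum(ratio), 0.90) + 1)
        assert n_keep == 3


class TestLFMM:
    def test_null_flags_few(self, null_ds):
        gm = scan.filter_maf(null_ds.genotypes)
        res = scan.lfmm_scan(gm, env_pcs_for(null_ds, gm), K=5, replicates=3, seed=11)
        assert len(res.adaptive) / gm.n_loci <= 0.07

    def test_k0_equals_simple_regression(self):
        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, size=(40, 30)).astype(float)
        gm = make_gm(dosage)
        x = rng.normal(size=40)
        env = pd.DataFrame({"envPC1": x})
        res = scan.lfmm_scan(gm, env, K=0, replicates=1, seed=0)
        # closed form: per-locus OLS z of scaled dosage on standardized x
        Z = scan._scaled_matrix(gm)
        xs = (x - x.mean()) / x.std()
        b = xs @ Z / (xs @ xs)
        resid = Z - np.outer(xs, b)
        se = np.sqrt((resid**2).sum(0) / (40 - 2) / (xs @ xs))
        z = b / se
        lam = np.median(z**2) / stats.chi2.ppf(0.5, 1)
        np.testing.assert_allclose(
            res.table["stat"], (z / np.sqrt(lam)) ** 2, rtol=1e-6
        )

    def test_recall_on_clinal_fixture(self, clinal_ds):
        gm = scan.filter_maf(clinal_ds.genotypes)
        truth = set(clinal_ds.truth["adaptive_loci"]) & set(gm.locus_ids)
        res = scan.lfmm_scan(gm, env_pcs_for(clinal_ds, gm), K=3, replicates=3, seed=1)
        recall = len(res.adaptive & truth) / len(truth)
        pca = scan.pcadapt_scan(gm, K=3)
        recall_pca = len(pca.adaptive & truth) / len(truth)
        assert recall >= recall_pca - 0.2


class TestUnion:
    def make(self, flagged, universe):
        table = pd.DataFrame(
            {
                "locus": list(universe),
                "stat": 0.0,
                "p": 0.5,
                "q": 0.5,
                "flagged": [u in flagged for u in universe],
            }
        )
        return scan.ScanResult(table, 1, 1.0, "x", set(flagged))

    def test_disjoint_and_identical(self):
        uni = [str(i) for i in range(10)]
        a = self.make({"1", "2"}, uni)
        b = self.make({"3"}, uni)
        u, rep = scan.union_adaptive(a, b)
        assert u == {"1", "2", "3"} and rep["intersection"] == 0
        u2, rep2 = scan.union_adaptive(a, a)
        assert u2 == {"1", "2"} and rep2["intersection"] == 2

    def test_study_sized_overlap_arithmetic(self):
        uni = [f"L{i}" for i in range(2000)]
        a_set = set(uni[:273])
        b_set = set(uni[241:1301])  # overlap of 32 with a_set
        a, b = self.make(a_set, uni), self.make(b_set, uni)
        u, rep = scan.union_adaptive(a, b)
        assert rep["intersection"] == 32
        assert len(u) == 1301


class TestBH:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_brute_force(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), brute_force_bh(pvals), rtol=1e-10
        )

    def test_qvalues_monotone_in_p(self, null_ds):
        gm = scan.filter_maf(null_ds.genotypes.subset_loci(np.arange(200)))
        res = scan.pcadapt_scan(gm, K=3)
        t = res.table.sort_values("p")
        assert (np.diff(t["q"]) >= -1e-12).all()
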