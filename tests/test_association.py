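import numpy as np
import pandas as pd
import pytest

from corecurator import association as assoc
from corecurator import simulate as sim
from corecurator.containers import GeneticMap, GenotypeMatrix, MembershipMatrix


class TestKinship:
    def test_two_accession_example(self):
        # calls [[0,1],[1,0]]: p=(0.5,0.5), W=+-0.5, K = [[1,-1],[-1,1]]/1 * ...
        G = GenotypeMatrix(["a", "b"], ["m1", "m2"], np.array([[0.0, 1], [1, 0]]))
        K = assoc.kinship(G, maf_min=0.0)
        # denom = 2 * 0.25 = 0.5 ; W W^T diag = 0.5 -> K = [[1,-1],[-1,1]]
        np.testing.assert_allclose(K.values, [[1, -1], [-1, 1]])

    def test_duplicates_maximal_similarity(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, (5, 200)).astype(float)
        calls[1] = calls[0]
        G = GenotypeMatrix([f"a{i}" for i in range(5)], [f"m{j}" for j in range(200)], calls)
        K = assoc.kinship(G)
        off = K.values - np.diag(np.diag(K.values))
        assert K.values[0, 1] == pytest.approx(K.values[0, 0])
        assert K.values[0, 1] >= off.max() - 1e-12

    def test_marker_doubling_invariance(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, (6, 50)).astype(float)
        G1 = GenotypeMatrix([f"a{i}" for i in range(6)], [f"m{j}" for j in range(50)], calls)
        G2 = GenotypeMatrix(
            [f"a{i}" for i in range(6)],
            [f"m{j}" for j in range(100)],
            np.hstack([calls, calls]),
        )
        np.testing.assert_allclose(assoc.kinship(G1).values, assoc.kinship(G2).values)

    def test_accession_order_invariance(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 2, (8, 60)).astype(float)
        ids = [f"a{i}" for i in range(8)]
        G = GenotypeMatrix(ids, [f"m{j}" for j in range(60)], calls)
        perm = rng.permutation(8)
        Gp = G.subset(accession_idx=perm)
        K = assoc.kinship(G).values
        Kp = assoc.kinship(Gp).values
        np.testing.assert_allclose(K[np.ix_(perm, perm)], Kp, atol=1e-12)

    def test_maf_filter_empty(self):
        G = GenotypeMatrix(["a", "b"], ["m"], np.array([[1.0], [1.0]]))
        with pytest.raises(ValueError, match="MAF"):
            assoc.kinship(G)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            assoc.KinshipMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]), 1, 0.0)


class TestMLMScan:
    def _identity_setup(self, seed=0, n=120, m=60, beta=1.2):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, (n, m)).astype(float)
        ids = [f"a{i}" for i in range(n)]
        G = GenotypeMatrix(ids, [f"m{j}" for j in range(m)], calls)
        y = pd.Series(beta * calls[:, 5] + rng.normal(0, 1, n), index=ids)
        K = assoc.KinshipMatrix(ids, np.eye(n), n_markers=m, maf_min=0.0)
        return G, y, K

    def test_identity_kinship_matches_ols(self):
        """With K = I and delta large the GLS collapses to OLS: dual route
        via statsmodels per-marker regression."""
        import statsmodels.api as sm

        G, y, K = self._identity_setup()
        res = assoc.mlm_scan(G, y, None, K)
        # oracle: plain OLS t-test per marker (mixed model with K=I is
        # weighted by a constant, leaving identical t statistics)
        for j in [0, 5, 20]:
            x = G.calls[:, j]
            fit = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
            row = res[res["marker"] == f"m{j}"].iloc[0]
            assert row["p"] == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_causal_marker_top_hit(self):
        G, y, K = self._identity_setup(beta=2.0)
        res = assoc.mlm_scan(G, y, None, K)
        assert res.loc[res["p"].idxmin(), "marker"] == "m5"
        assert res.loc[res["marker"] == "m5", "q"].iloc[0] < 0.05

    def test_minor_allele_effect_reported(self):
        rng = np.random.default_rng(3)
        n = 100
        x = (rng.random(n) < 0.8).astype(float)  # allele 1 is major
        calls = np.column_stack([x, rng.integers(0, 2, (n, 20)).astype(float)])
        ids = [f"a{i}" for i in range(n)]
        G = GenotypeMatrix(ids, [f"m{j}" for j in range(21)], calls)
        y = pd.Series(1.5 * x + rng.normal(0, 0.5, n), index=ids)
        K = assoc.KinshipMatrix(ids, np.eye(n), 21, 0.0)
        res = assoc.mlm_scan(G, y, None, K)
        row = res[res["marker"] == "m0"].iloc[0]
        assert row["allele"] == "0" and row["effect"] == pytest.approx(-1.5, abs=0.4)
        assert row["maf"] <= 0.5

    def test_q_covariate_accepted_and_degenerate_dropped(self):
        G, y, K = self._identity_setup(seed=4, n=60, m=30)
        q = np.full((60, 2), 0.5)  # degenerate: collinear with intercept
        Q = MembershipMatrix(list(G.accessions), q)
        res = assoc.mlm_scan(G, y, Q, K)
        assert len(res) > 0 and res["p"].notna().all()

    def test_structured_sim_detects_qtl(self):
        cfg = sim.SimulationConfig(
            seed=41, n_per_subpop=[40, 40, 40, 40, 40], n_admixed=0,
            n_markers=400, missing_rate=0.0, qtl_spec=[(200, 1.5)],
            heritability=0.6,
        )
        G, truth = sim.generate_genotypes(cfg, sim.generate_map(cfg))
        y = sim.generate_phenotype(G, truth, cfg)
        K = assoc.kinship(G)
        Q = truth.true_q
        res = assoc.mlm_scan(G, y, Q, K)
        assert res.loc[res["p"].idxmin(), "marker"] == G.markers[200]

    def test_constant_phenotype_rejected(self):
        G, y, K = self._identity_setup(n=20, m=10)
        with pytest.raises(ValueError, match="constant"):
            assoc.mlm_scan(G, pd.Series(1.0, index=G.accessions), None, K)

    def test_disjoint_accessions_rejected(self):
        G, y, K = self._identity_setup(n=20, m=10)
        y.index = [f"z{i}" for i in range(20)]
        with pytest.raises(ValueError, match="too few"):
            assoc.mlm_scan(G, y, None, K)


class TestGenomicInflation:
    def test_uniform_near_one(self):
        rng = np.random.default_rng(0)
        lam = assoc.genomic_inflation(rng.random(20000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_median_half_exactly_one(self):
        assert assoc.genomic_inflation([0.5, 0.5, 0.5]) == pytest.approx(1.0)


class TestBHFDR:
    def test_hand_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # sorted: .005 .01 .03 .04 -> ratios .02 .02 .04 .04
        np.testing.assert_allclose(assoc.bh_fdr(p), [0.02, 0.04, 0.04, 0.02])

    def test_monotone_and_capped(self):
        q = assoc.bh_fdr(np.array([0.9, 0.95, 0.99]))
        assert (q <= 1).all()
        order = np.argsort([0.9, 0.95, 0.99])
        assert (np.diff(q[order]) >= 0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500) ** 2
        np.testing.assert_allclose(
            assoc.bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_brute_force_definition(self):
        """Oracle: q_i = min over thresholds t >= p_i of m*t/#{p <= t}."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(rng.integers(2, 12))
            q = assoc.bh_fdr(p)
            m = len(p)
            for i in range(m):
                cands = [m * t / np.sum(p <= t) for t in p if t >= p[i]]
                assert q[i] == pytest.approx(min(min(cands), 1.0), abs=1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            assoc.bh_fdr([0.1, np.nan])
        with pytest.raises(ValueError):
            assoc.bh_fdr([-0.1, 0.5])


class TestManhattan:
    def _results(self):
        return pd.DataFrame(
            {
                "marker": ["m2", "m1", "mx"],
                "effect": [0.1, 0.2, 0.3],
                "allele": ["1", "0", "1"],
                "maf": [0.2, 0.3, 0.4],
                "p": [0.001, 0.5, 0.02],
                "q": [0.003, 0.5, 0.05],
                "neg_log10_q": [2.52, 0.3, 1.3],
            }
        )

    def _map(self):
        return GeneticMap(
            pd.DataFrame(
                {"marker": ["m1", "m2"], "chrom": ["1H", "1H"], "cM": [1.0, 5.0]}
            )
        )

    def test_sorted_unmapped_last(self):
        out = assoc.manhattan_table(self._results(), self._map())
        assert out["marker"].tolist() == ["m1", "m2", "mx"]
        assert out["unmapped"].tolist() == [False, False, True]

    def test_boundary_q_not_significant(self):
        out = assoc.manhattan_table(self._results(), self._map(), alpha=0.05)
        assert not out.loc[out["marker"] == "mx", "significant"].iloc[0]
        assert out.loc[out["marker"] == "m2", "significant"].iloc[0]

    def test_empty_results(self):
        empty = self._results().iloc[0:0]
        out = assoc.manhattan_table(empty, self._map())
        assert len(out) == 0
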