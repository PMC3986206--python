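import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corecurator import ld, simulate as sim
from corecurator.containers import GeneticMap, GenotypeMatrix
from corecurator.structure import pca_genotypes


def _map_df(markers, chroms, cms):
    return GeneticMap(pd.DataFrame({"marker": markers, "chrom": chroms, "cM": cms}))


class TestPairR2:
    def test_hand_example(self):
        # pA=0.5, pB=0.5, D = 0.4-0.25 = 0.15 -> r2 = 0.0225/0.0625 = 0.36
        x = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], float)
        y = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0], float)
        r2, n = ld.pair_r2(x, y)
        assert n == 10
        assert r2 == pytest.approx(0.36)

    def test_identical_and_complement_one(self):
        x = np.array([0, 1, 0, 1, 1], float)
        assert ld.pair_r2(x, x)[0] == pytest.approx(1.0)
        assert ld.pair_r2(x, 1 - x)[0] == pytest.approx(1.0)

    def test_equilibrium_zero(self):
        x = np.array([0, 0, 1, 1], float)
        y = np.array([0, 1, 0, 1], float)
        assert ld.pair_r2(x, y)[0] == pytest.approx(0.0)

    def test_monomorphic_flagged(self):
        x = np.zeros(5)
        y = np.array([0, 1, 0, 1, 1], float)
        r2, n = ld.pair_r2(x, y)
        assert np.isnan(r2) and n == 5

    def test_pairwise_complete(self):
        x = np.array([0, 1, np.nan, 1], float)
        y = np.array([0, 1, 1, np.nan], float)
        r2, n = ld.pair_r2(x, y)
        assert n == 2 and r2 == pytest.approx(1.0)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, (40, 12)).astype(float)
        calls[rng.random((40, 12)) < 0.1] = np.nan
        ia = np.array([0, 1, 2, 3, 4])
        ib = np.array([5, 6, 7, 8, 9])
        vec, nn = ld.r2_pairs(calls, ia, ib)
        for k, (a, b) in enumerate(zip(ia, ib)):
            r, n = ld.pair_r2(calls[:, a], calls[:, b])
            assert nn[k] == n
            if np.isnan(r):
                assert np.isnan(vec[k])
            else:
                assert vec[k] == pytest.approx(r)


class TestFisher:
    def test_matches_hypergeometric_enumeration(self):
        """Oracle: enumerate all 2x2 tables with the observed margins."""
        x = np.array([0] * 6 + [1] * 8, float)
        y = np.array([0, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 1, 1, 1], float)
        p = ld.pair_fisher_p(x, y)
        a_obs = int(np.sum((x == 0) & (y == 0)))
        r1 = int(np.sum(x == 0))
        c1 = int(np.sum(y == 0))
        n = len(x)
        probs = {
            a: stats.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        }
        p_obs = probs[a_obs]
        p_brute = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(p_brute, rel=1e-9)

    def test_independent_p_one(self):
        x = np.array([0, 0, 1, 1], float)
        y = np.array([0, 1, 0, 1], float)
        assert ld.pair_fisher_p(x, y) == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        x = np.zeros(6)
        y = np.array([0, 1, 0, 1, 0, 1], float)
        with pytest.raises(ValueError, match="empty row or column"):
            ld.pair_fisher_p(x, y)


@pytest.fixture(scope="module")
def unstructured():
    cfg = sim.SimulationConfig(
        seed=31, n_subpops=1, n_per_subpop=[250], n_admixed=0,
        fst_per_subpop=[0.1], n_markers=1200, missing_rate=0.0,
        ld_decay_cM=0.0,
    )
    gm = sim.generate_map(cfg)
    G, _ = sim.generate_genotypes(cfg, gm)
    return G, gm


class TestThreshold:
    def test_threshold_near_empirical_quantile(self, unstructured):
        """Without structure or LD the parametric percentile should sit
        close to the empirical one."""
        G, gm = unstructured
        thr = ld.unlinked_threshold(G, gm, n_pairs=20000, seed=0)
        # empirical q99 of a fresh unlinked sample
        rng = np.random.default_rng(1)
        pos = gm.positions(G.markers)
        chrom = pos["chrom"].to_numpy()
        ia = rng.integers(0, G.n_markers, 40000)
        ib = rng.integers(0, G.n_markers, 40000)
        keep = chrom[ia] != chrom[ib]
        r2, _ = ld.r2_pairs(G.calls, ia[keep], ib[keep])
        q99 = np.nanquantile(r2, 0.99)
        assert thr.threshold == pytest.approx(q99, abs=0.01)
        assert 0 <= thr.threshold <= 1

    def test_median_percentile(self, unstructured):
        G, gm = unstructured
        thr = ld.unlinked_threshold(G, gm, n_pairs=20000, percentile=50.0, seed=0)
        rng = np.random.default_rng(2)
        pos = gm.positions(G.markers)
        chrom = pos["chrom"].to_numpy()
        ia = rng.integers(0, G.n_markers, 40000)
        ib = rng.integers(0, G.n_markers, 40000)
        keep = chrom[ia] != chrom[ib]
        r2, _ = ld.r2_pairs(G.calls, ia[keep], ib[keep])
        assert thr.threshold == pytest.approx(np.nanmedian(r2), abs=0.005)

    def test_deterministic(self, unstructured):
        G, gm = unstructured
        a = ld.unlinked_threshold(G, gm, n_pairs=5000, seed=7)
        b = ld.unlinked_threshold(G, gm, n_pairs=5000, seed=7)
        assert a.threshold == b.threshold and a.boxcox_lambda == b.boxcox_lambda

    def test_bad_percentile(self, unstructured):
        G, gm = unstructured
        with pytest.raises(ValueError, match="percentile"):
            ld.unlinked_threshold(G, gm, percentile=100.0)

    def test_single_chromosome_rejected(self):
        calls = np.random.default_rng(0).integers(0, 2, (30, 20)).astype(float)
        G = GenotypeMatrix([f"a{i}" for i in range(30)], [f"m{j}" for j in range(20)], calls)
        gm = _map_df(G.markers, ["1H"] * 20, np.linspace(0, 100, 20))
        with pytest.raises(ValueError, match="2 chromosomes"):
            ld.unlinked_threshold(G, gm)


class TestDecay:
    def test_decay_ordering_between_chains(self):
        """Longer copy-chain persistence yields slower r^2 decay."""
        means = {}
        for lam in (1.0, 6.0):
            cfg = sim.SimulationConfig(
                seed=12, n_subpops=1, n_per_subpop=[200], n_admixed=0,
                fst_per_subpop=[0.1], n_markers=800, missing_rate=0.0,
                ld_decay_cM=lam,
            )
            gm = sim.generate_map(cfg)
            G, _ = sim.generate_genotypes(cfg, gm)
            prof = ld.decay_profile(G, gm, max_distance_cM=10.0, bin_width_cM=2.0)
            agg = prof.groupby("bin_lo_cM").apply(
                lambda d: np.average(
                    d["mean_r2"].fillna(0), weights=d["n_pairs"].clip(lower=0) + 1e-9
                ),
                include_groups=False,
            )
            means[lam] = agg
        assert (means[6.0].iloc[1:] > means[1.0].iloc[1:]).all()
        # and decay is monotone-ish for the persistent chain
        assert means[6.0].iloc[0] > means[6.0].iloc[-1]

    def test_empty_bins_reported(self):
        calls = np.random.default_rng(1).integers(0, 2, (20, 3)).astype(float)
        G = GenotypeMatrix([f"a{i}" for i in range(20)], ["m1", "m2", "m3"], calls)
        gm = _map_df(G.markers, ["1H", "1H", "1H"], [0.0, 0.5, 20.0])
        prof = ld.decay_profile(G, gm, max_distance_cM=5.0, bin_width_cM=1.0, maf_min=0.0)
        row = prof[(prof["bin_lo_cM"] == 3.0)]
        assert row["n_pairs"].iloc[0] == 0 and np.isnan(row["mean_r2"].iloc[0])
        near = prof[prof["bin_lo_cM"] == 0.0]
        assert near["n_pairs"].iloc[0] == 1


class TestLogistic:
    def test_null_pair_large_p(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200).astype(float)
        x = rng.integers(0, 2, 200).astype(float)
        p, method = ld.logistic_pair_p(y, x)
        assert p > 0.01 and method == "ml"

    def test_identical_regressor_capped(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100).astype(float)
        p, method = ld.logistic_pair_p(y, y)
        assert method == "firth"  # complete separation falls back
        assert ld.neg_log10(p) > 10

    def test_constant_response_degenerate(self):
        y = np.zeros(50)
        x = np.random.default_rng(2).integers(0, 2, 50).astype(float)
        p, method = ld.logistic_pair_p(y, x)
        assert np.isnan(p) and method == "degenerate"

    def test_matches_statsmodels_lrt(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 300).astype(float)
        z = rng.normal(size=300)
        eta = -0.2 + 0.8 * x + 0.5 * z
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        p, method = ld.logistic_pair_p(y, x, z.reshape(-1, 1))
        X_full = sm.add_constant(np.column_stack([x, z]))
        X_red = sm.add_constant(z)
        llf = sm.Logit(y, X_full).fit(disp=0).llf
        llr = sm.Logit(y, X_red).fit(disp=0).llf
        p_ref = stats.chi2.sf(2 * (llf - llr), 1)
        assert method == "ml" and p == pytest.approx(p_ref, rel=1e-6)

    def test_neg_log10_ceiling(self):
        assert ld.neg_log10(0.0) == ld.NEG_LOG10_CEILING
        assert ld.neg_log10(1e-400) == ld.NEG_LOG10_CEILING
        assert ld.neg_log10(0.01) == pytest.approx(2.0)
        assert np.isnan(ld.neg_log10(np.nan))


class TestLogisticScan:
    def test_window_half_open_and_leftmost(self):
        rng = np.random.default_rng(4)
        n = 60
        calls = rng.integers(0, 2, (n, 5)).astype(float)
        G = GenotypeMatrix(
            [f"a{i}" for i in range(n)], [f"m{j}" for j in range(5)], calls
        )
        gm = _map_df(G.markers, ["1H"] * 5, [0.0, 1.0, 2.0, 3.5, 50.0])
        pca = pca_genotypes(G, 2, maf_min=0.0)
        scan = ld.logistic_ld_scan(G, gm, pca, n_pcs=2, window=(1.0, 2.0), maf_min=0.0)
        pairs = set(zip(scan["marker_a"], scan["marker_b"]))
        # [1,2) windows: m0->m1 (d=1), m1->m2 (d=1), m2->m3 (d=1.5); d=2 excluded
        assert pairs == {("m0", "m1"), ("m1", "m2"), ("m2", "m3")}
        assert (scan["dist_cM"] >= 1).all() and (scan["dist_cM"] < 2).all()

    def test_empty_window_ok(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, (30, 3)).astype(float)
        G = GenotypeMatrix([f"a{i}" for i in range(30)], ["m0", "m1", "m2"], calls)
        gm = _map_df(G.markers, ["1H"] * 3, [0.0, 10.0, 20.0])
        pca = pca_genotypes(G, 2, maf_min=0.0)
        scan = ld.logistic_ld_scan(G, gm, pca, n_pcs=2, window=(1.0, 2.0), maf_min=0.0)
        assert len(scan) == 0

    def test_bad_window(self, small_sim):
        _, gm, G, _ = small_sim
        pca = pca_genotypes(G, 3)
        with pytest.raises(ValueError, match="window"):
            ld.logistic_ld_scan(G, gm, pca, n_pcs=3, window=(2.0, 1.0))

    def test_too_few_pcs(self, small_sim):
        _, gm, G, _ = small_sim
        pca = pca_genotypes(G, 3)
        with pytest.raises(ValueError, match="components"):
            ld.logistic_ld_scan(G, gm, pca, n_pcs=11)


def test_min_p_per_response():
    scan = pd.DataFrame(
        {
            "marker_a": ["m0", "m0", "m1"],
            "marker_b": ["m1", "m2", "m2"],
            "p_logistic": [0.5, 0.01, 0.2],
        }
    )
    best = ld.min_p_per_response(scan)
    assert len(best) == 2
    assert best.loc[best["marker_a"] == "m0", "marker_b"].iloc[0] == "m2"
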