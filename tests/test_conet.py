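"""Correlation network: brute-force Pearson agreement, strict edge
thresholds, the connectivity cascade, biclustering against a
hand-computed linkage, and planted-module recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnctox.conet import (
    NetThresholds,
    bicluster_network,
    correlation_profiles,
    degree_filter,
    edge_matrix,
    linked_mrna_cluster,
    pearson_edges,
    select_top_clusters,
)
from lnctox.core import LnctoxError


def _profiles(X, prefix):
    X = np.asarray(X, float)
    return pd.DataFrame(
        X,
        index=[f"{prefix}{i}" for i in range(X.shape[0])],
        columns=[f"g{j}" for j in range(X.shape[1])],
    )


def brute_force_edges(L, M, th):
    """O(n^2) reference using scipy.stats.pearsonr pair by pair."""
    rows = []
    for li, lrow in L.iterrows():
        for mi, mrow in M.iterrows():
            if lrow.std() == 0 or mrow.std() == 0:
                continue
            r, p = stats.pearsonr(lrow, mrow)
            if abs(r) > th.min_abs_r and p < th.max_p:
                rows.append((li, mi, r, p))
    return rows


class TestPearsonEdges:
    def test_identical_and_negated_profiles_kept(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 16)
        L = _profiles([base], "l")
        M = _profiles([base, -base], "m")
        edges = pearson_edges(L, M)
        assert len(edges) == 2
        r = edges.set_index("mrna_id")["r"]
        assert r["m0"] == pytest.approx(1.0)
        assert r["m1"] == pytest.approx(-1.0)

    def test_strict_threshold_boundary(self):
        """r = 0.8 exactly is excluded; r = 0.81 at n=16 has p ~ 1.5e-4."""
        n = 16
        t = 0.81 * np.sqrt((n - 2) / (1 - 0.81**2))
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(1.5e-4, rel=0.1)
        th = NetThresholds()
        # construct profile pairs with r exactly 0.8 / 0.81 via 2-d rotation
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (z @ x) / (x @ x)  # orthogonalize
        z /= z.std()
        for r_target, expect in [(0.8, 0), (0.81, 1)]:
            y = r_target * x + np.sqrt(1 - r_target**2) * z
            edges = pearson_edges(_profiles([x], "l"), _profiles([y], "m"), th)
            assert len(edges) == expect

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (5, 12))
        L = _profiles(
            np.vstack([base + 0.3 * rng.normal(0, 1, (5, 12)) for _ in range(4)]), "l"
        )
        M = _profiles(
            np.vstack([base + 0.3 * rng.normal(0, 1, (5, 12)) for _ in range(6)]), "m"
        )
        th = NetThresholds(min_abs_r=0.5, max_p=0.1, min_degree=1)
        mine = pearson_edges(L, M, th)
        ref = brute_force_edges(L, M, th)
        assert len(mine) == len(ref)
        mine_map = {(a, b): r for a, b, r in zip(mine.lnc_id, mine.mrna_id, mine.r)}
        for li, mi, r, _p in ref:
            assert abs(mine_map[(li, mi)] - r) < 1e-12

    def test_zero_variance_profile_skipped(self):
        L = _profiles([[1.0] * 8], "l")
        M = _profiles([np.arange(8.0)], "m")
        assert len(pearson_edges(L, M)) == 0

    def test_too_few_contrasts_error(self):
        with pytest.raises(LnctoxError):
            pearson_edges(_profiles([[1, 2]], "l"), _profiles([[1, 2]], "m"))


class TestDegreeFilter:
    def _edges(self, degrees: dict[str, int]):
        rows = []
        for lnc, deg in degrees.items():
            for i in range(deg):
                rows.append(
                    {"lnc_id": lnc, "mrna_id": f"m_{lnc}_{i}", "r": 0.9, "p": 1e-5, "n": 16}
                )
        return pd.DataFrame(rows)

    def test_boundary_15(self):
        kept, _, _ = degree_filter(self._edges({"l14": 14, "l15": 15}))
        assert kept == {"l15"}

    def test_mrna_cascade(self):
        edges = self._edges({"l14": 14, "l15": 15})
        _, kept_mrna, sub = degree_filter(edges)
        assert all(m.startswith("m_l15") for m in kept_mrna)
        assert len(sub) == 15

    def test_monotone_in_min_degree(self):
        edges = self._edges({f"l{d}": d for d in range(10, 30)})
        sizes = [
            len(degree_filter(edges, NetThresholds(min_degree=d))[0])
            for d in (5, 10, 15, 20, 25)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestBicluster:
    def test_hand_computed_average_linkage(self):
        """4 items at 1-d positions 0, 1, 10, 12: merges at heights
        1, 2, then mean(10, 12, 9, 11) = 10.5."""
        mat = np.zeros((4, 4))
        mat[:, 0] = [0.0, 1.0, 10.0, 12.0]
        edges = pd.DataFrame(
            {
                "lnc_id": [f"l{i}" for i in range(4)],
                "mrna_id": ["m0"] * 4,
                "r": mat[:, 0],
                "p": 1e-6,
                "n": 16,
            }
        )
        # build through the public API with a padded mRNA axis
        for j in range(1, 4):
            edges = pd.concat(
                [
                    edges,
                    pd.DataFrame(
                        {
                            "lnc_id": [f"l{i}" for i in range(4)],
                            "mrna_id": [f"m{j}"] * 4,
                            "r": 0.0,
                            "p": 1.0,
                            "n": 16,
                        }
                    ),
                ]
            )
        lnc_cl, _ = bicluster_network(
            edges[edges.r != 0.0],
            {f"l{i}" for i in range(4)},
            {f"m{j}" for j in range(4)},
            k_lnc=2,
            k_mrna=1,
        )
        Z = lnc_cl.linkage
        assert Z[0][2] == pytest.approx(1.0)
        assert Z[1][2] == pytest.approx(2.0)
        assert Z[2][2] == pytest.approx(10.5)
        # clusters: {l0, l1} vs {l2, l3}; sizes tie -> tighter cluster is id 1
        assert set(lnc_cl.members(1)) == {"l0", "l1"}
        assert set(lnc_cl.members(2)) == {"l2", "l3"}

    def test_anti_correlated_modules_give_opposite_sign_blocks(self):
        rng = np.random.default_rng(3)
        v = np.where(rng.random(16) < 0.5, 2.0, 0.0)
        noise = lambda: 0.05 * rng.normal(0, 1, 16)
        L = _profiles([v + noise() for _ in range(6)] + [-v + noise() for _ in range(6)], "l")
        M = _profiles([v + noise() for _ in range(10)], "m")
        th = NetThresholds(min_degree=5)
        edges = pearson_edges(L, M, th)
        kept_l, kept_m, edges = degree_filter(edges, th)
        lnc_cl, mrna_cl = bicluster_network(edges, kept_l, kept_m, k_lnc=2, k_mrna=1)
        mat = edge_matrix(edges, kept_l, kept_m)
        means = [mat.loc[lnc_cl.members(c)].to_numpy().mean() for c in (1, 2)]
        assert np.sign(means[0]) != np.sign(means[1])
        assert {len(lnc_cl.members(1)), len(lnc_cl.members(2))} == {6}

    def test_k_too_large_errors(self):
        edges = pd.DataFrame(
            {"lnc_id": ["l0"], "mrna_id": ["m0"], "r": [0.9], "p": [1e-5], "n": 16}
        )
        with pytest.raises(LnctoxError, match="exceeds"):
            bicluster_network(edges, {"l0"}, {"m0"}, k_lnc=3, k_mrna=1)


class TestTopClusters:
    def test_sizes_rank_selection(self):
        labels = pd.Series(
            [1] * 205 + [2] * 121 + [3] * 10,
            index=[f"l{i}" for i in range(336)],
        )
        from lnctox.conet import ClusterAssignment

        cl = ClusterAssignment(labels=labels, axis="lncRNA")
        top = select_top_clusters(cl, n_top=2)
        assert top == [1, 2]
        assert len(cl.members(1)) == 205 and len(cl.members(2)) == 121

    def test_single_cluster_warns(self):
        from lnctox.conet import ClusterAssignment

        cl = ClusterAssignment(
            labels=pd.Series([1, 1], index=["a", "b"]), axis="lncRNA"
        )
        with pytest.warns(UserWarning):
            assert select_top_clusters(cl, n_top=2) == [1]


def test_planted_module_recovery(small_contrasts, preprocessed):
    """Profiles of planted module members correlate > 0.95 and the
    module survives edge + degree filtering largely intact."""
    contrasts, gated = small_contrasts
    m, design, truth, cfg = preprocessed
    de_lnc = set().union(*(g[0] for g in gated.values()))
    de_mrna = set().union(*(g[1] for g in gated.values()))
    L, M = correlation_profiles(contrasts, de_lnc, de_mrna)
    assert L.shape[1] == 16
    module_lnc = [p for p in L.index if p in truth.module_assignment]
    assert len(module_lnc) >= 0.8 * cfg.module_size[0] * cfg.n_modules
    edges = pearson_edges(L, M)
    kept_l, kept_m, edges = degree_filter(edges)
    found = set(zip(edges["lnc_id"], edges["mrna_id"]))
    true_found = found & truth.true_edges
    assert len(true_found) / max(len(found), 1) > 0.8  # precision
    detectable = {
        (a, b) for a, b in truth.true_edges if a in L.index and b in M.index
    }
    assert len(true_found) / len(detectable) > 0.8  # recall among DE-recovered


def test_low_noise_module_profiles_near_identical():
    """In a low-noise simulation, planted-module member profiles
    correlate above 0.95 pairwise."""
    from lnctox.diffexpr import gate_de, run_contrasts
    from lnctox.preprocess import preprocess_chain
    from lnctox.simulate import simulate_experiment

    from conftest import small_config

    cfg = small_config(seed=21, noise_sd=0.1)
    m, design, _, truth = (lambda t: (t[0], t[1], t[2], t[3]))(simulate_experiment(cfg))
    mp = preprocess_chain(m, design)
    contrasts = run_contrasts(mp, design)
    gated = {g: gate_de(r) for g, r in contrasts.items()}
    de_lnc = set().union(*(g[0] for g in gated.values()))
    L, _ = correlation_profiles(contrasts, de_lnc, set())
    module_lnc = [p for p in L.index if p in truth.module_assignment]
    mid = truth.module_assignment[module_lnc[0]]
    peers = [p for p in module_lnc if truth.module_assignment[p] == mid][:10]
    corr = np.corrcoef(L.loc[peers].to_numpy())
    assert corr[np.triu_indices_from(corr, 1)].min() > 0.95


def test_two_dominant_modules_fill_top_clusters():
    """With two planted modules and the tree cut to match, the top-two
    clusters are each dominated by one module and jointly hold > 90% of
    retained lncRNAs."""
    from lnctox.diffexpr import gate_de, run_contrasts
    from lnctox.preprocess import preprocess_chain
    from lnctox.simulate import simulate_experiment

    from conftest import small_config

    cfg = small_config(seed=31, frac_de=0.01)
    m, design, _, truth = simulate_experiment(cfg)
    mp = preprocess_chain(m, design)
    contrasts = run_contrasts(mp, design)
    gated = {g: gate_de(r) for g, r in contrasts.items()}
    de_lnc = set().union(*(g[0] for g in gated.values()))
    de_mrna = set().union(*(g[1] for g in gated.values()))
    L, M = correlation_profiles(contrasts, de_lnc, de_mrna)
    kept_l, kept_m, edges = degree_filter(pearson_edges(L, M))
    lnc_cl, _ = bicluster_network(edges, kept_l, kept_m, k_lnc=2, k_mrna=2)
    top = select_top_clusters(lnc_cl, n_top=2)
    mass = sum(len(lnc_cl.members(c)) for c in top)
    assert mass / len(kept_l) > 0.9
    majorities = []
    for c in top:
        mods = [truth.module_assignment.get(p) for p in lnc_cl.members(c)]
        counts = pd.Series(mods).value_counts()
        majorities.append(counts.idxmax())
        assert counts.max() / len(mods) > 0.9  # module-pure cluster
    assert set(majorities) == {0, 1}  # one cluster per planted module


def test_transcript_not_de_anywhere_excluded(small_contrasts):
    contrasts, _ = small_contrasts
    L, M = correlation_profiles(contrasts, {"lnc_00000"}, set())
    assert set(L.index) <= {"lnc_00000"}
    assert M.empty
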