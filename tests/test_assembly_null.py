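"""betaMNTD / betaNTI / RC-bray: oracle equivalence, calibration and the
five-process classification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

import microbiogeo as mb
from microbiogeo.assembly_null import PROCESSES


def _brute_force_bmntd(a: pd.Series, b: pd.Series, tree, weighted=True) -> float:
    """Independent oracle: cophenetic distances from explicit LCA depths."""
    depth = {}
    for tip in tree.tips():
        depth[tip.name] = tip.accumulate_to_ancestor(tree)

    def coph(x, y):
        if x == y:
            return 0.0
        lca = tree.lca([x, y])
        lca_depth = lca.accumulate_to_ancestor(tree) if lca is not tree else 0.0
        return depth[x] + depth[y] - 2 * lca_depth

    ia, ib = a[a > 0], b[b > 0]

    def directional(src, dst):
        w = src / src.sum() if weighted else pd.Series(1 / len(src), index=src.index)
        return sum(
            w[t] * min(coph(t, u) for u in dst.index) for t in src.index
        )

    return 0.5 * (directional(ia, ib) + directional(ib, ia))


class TestBmntd:
    def test_identical_communities_zero(self, quartet_tree):
        a = pd.Series({"A": 3.0, "C": 1.0})
        assert mb.bmntd(a, a, quartet_tree) == pytest.approx(0.0)

    def test_single_taxon_pair(self, quartet_tree):
        a = pd.Series({"A": 1.0})
        b = pd.Series({"C": 1.0})
        assert mb.bmntd(a, b, quartet_tree) == pytest.approx(4.0)

    def test_unweighted_equals_weighted_under_uniform_abundance(self, quartet_tree):
        a = pd.Series({"A": 2.0, "B": 2.0})
        b = pd.Series({"C": 2.0, "D": 2.0})
        w = mb.bmntd(a, b, quartet_tree, weighted=True)
        u = mb.bmntd(a, b, quartet_tree, weighted=False)
        assert w == pytest.approx(u)

    def test_empty_sample_rejected(self, quartet_tree):
        with pytest.raises(mb.ParameterError):
            mb.bmntd(pd.Series({"A": 0.0}), pd.Series({"C": 1.0}), quartet_tree)

    @pytest.mark.parametrize("weighted", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed, weighted):
        """Oracle equivalence on random <=6-taxon trees to 1e-12."""
        rng = np.random.default_rng(seed)
        tree = mb.simulate_phylogeny(6, seed=seed)
        taxa = [t.name for t in tree.tips()]
        a = pd.Series(rng.integers(0, 5, size=6).astype(float), index=taxa)
        b = pd.Series(rng.integers(0, 5, size=6).astype(float), index=taxa)
        if (a > 0).sum() == 0:
            a.iloc[0] = 1.0
        if (b > 0).sum() == 0:
            b.iloc[1] = 1.0
        ours = mb.bmntd(a, b, tree, weighted=weighted)
        oracle = _brute_force_bmntd(a, b, tree, weighted=weighted)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matrix_agrees_with_pairwise(self, quartet_tree):
        df = pd.DataFrame(
            {"s1": [4, 1, 0, 0], "s2": [0, 0, 3, 2], "s3": [1, 1, 1, 1]},
            index=list("ABCD"),
        )
        table = mb.CountTable(df)
        M = mb.bmntd_matrix(table, quartet_tree)
        for u, v in itertools.combinations(table.samples, 2):
            direct = mb.bmntd(
                df[u].astype(float), df[v].astype(float), quartet_tree
            )
            assert M.loc[u, v] == pytest.approx(direct, abs=1e-12)


class TestBnti:
    def test_seed_determinism(self):
        tree = mb.simulate_phylogeny(20, seed=4)
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 10, size=(20, 4)) + (rng.random((20, 4)) < 0.2),
            index=[t.name for t in tree.tips()],
            columns=list("wxyz"),
        ).astype(np.int64)
        df.iloc[0] += 1
        table = mb.CountTable(df)
        r1 = mb.bnti_all_pairs(table, tree, n_null=49, seed=7)
        r2 = mb.bnti_all_pairs(table, tree, n_null=49, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_branch_scale_invariance(self):
        """betaNTI is unchanged when every branch length is multiplied by a
        constant: observed and null scale together."""
        tree = mb.simulate_phylogeny(15, seed=6)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 7.5
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.integers(0, 6, size=(15, 5)),
            index=[t.name for t in tree.tips()],
            columns=list("abcde"),
        ).astype(np.int64)
        df.iloc[0] += 1
        table = mb.CountTable(df)
        r1 = mb.bnti_all_pairs(table, tree, n_null=99, seed=11)
        r2 = mb.bnti_all_pairs(table, scaled, n_null=99, seed=11)
        assert np.allclose(r1["bnti"], r2["bnti"], equal_nan=True)

    def test_star_like_null_flagged_not_dropped(self, caplog):
        """Identical samples leave no label-shuffle variance: betaNTI is NaN
        and reported, never silently removed."""
        tree = mb.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        df = pd.DataFrame({"s1": [1, 1, 1, 1], "s2": [1, 1, 1, 1]}, index=list("ABCD"))
        with caplog.at_level("WARNING", logger="microbiogeo"):
            res = mb.bnti_all_pairs(mb.CountTable(df), tree, n_null=19, seed=0)
        assert np.isnan(res["bnti"].iloc[0])
        assert "undefined" in caplog.text

    def test_self_null_calibration_smoke(self):
        """Randomly relabelled communities give betaNTI centred near 0 with
        roughly unit spread (small version of the full calibration)."""
        rng = np.random.default_rng(2024)
        tree = mb.simulate_phylogeny(60, seed=77)
        taxa = [t.name for t in tree.tips()]
        base = np.zeros((60, 8), dtype=np.int64)
        for j in range(8):
            members = rng.choice(60, size=20, replace=False)
            base[members, j] = rng.integers(1, 100, size=20)
        vals = []
        for rep in range(15):
            perm = rng.permutation(60)
            table = mb.CountTable(
                pd.DataFrame(base[perm], index=taxa, columns=[f"s{j}" for j in range(8)])
            )
            vals.append(mb.bnti_all_pairs(table, tree, n_null=99, seed=rep)["bnti"])
        vals = np.concatenate(vals)
        assert abs(np.nanmean(vals)) < 0.3
        assert 0.7 < np.nanstd(vals) < 1.3


class TestRcBray:
    def _pool_table(self, rng, n_taxa=20, n_samples=10):
        data = rng.integers(1, 50, size=(n_taxa, n_samples))
        return pd.DataFrame(
            data, index=[f"T{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )

    def test_disjoint_pair_hits_plus_one(self):
        """Observed dissimilarity of a fully disjoint pair exceeds every null
        assembled from a well-mixed pool."""
        rng = np.random.default_rng(5)
        df = self._pool_table(rng)
        df["x"] = 0
        df["y"] = 0
        df.loc[df.index[:10], "x"] = 50
        df.loc[df.index[10:], "y"] = 50
        rc = mb.rc_bray("x", "y", mb.CountTable(df), n_null=199, seed=1)
        assert rc == pytest.approx(1.0)

    def test_identical_pair_hits_minus_one(self):
        rng = np.random.default_rng(6)
        df = self._pool_table(rng)
        df["x"] = 0
        df.loc[df.index[:8], "x"] = rng.integers(10, 60, size=8)
        df["y"] = df["x"]
        rc = mb.rc_bray("x", "y", mb.CountTable(df), n_null=199, seed=2)
        assert rc == pytest.approx(-1.0)

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(7)
        df = self._pool_table(rng, n_taxa=15, n_samples=8)
        table = mb.CountTable(df)
        pairs = list(itertools.combinations(table.samples[:5], 2))
        rc = mb.rc_bray_pairs(table, pairs, n_null=49, seed=3)
        assert ((rc >= -1.0) & (rc <= 1.0)).all()

    def test_exchangeable_pairs_give_uniform_rc(self):
        """Communities generated by the null recipe itself produce RC values
        spread over [-1, 1]: mean |RC| near 0.5."""
        rng = np.random.default_rng(8)
        base = self._pool_table(rng, n_taxa=40, n_samples=12)
        occupancy = (base.to_numpy() > 0).sum(axis=1).astype(float)
        regional = base.to_numpy().sum(axis=1).astype(float)
        p_occ = occupancy / occupancy.sum()
        abs_rc = []
        for rep in range(200):
            df = base.copy()
            for name in ("x", "y"):
                drawn = rng.choice(40, size=15, replace=False, p=p_occ)
                comm = np.zeros(40, dtype=np.int64)
                comm[drawn] = rng.multinomial(300, regional[drawn] / regional[drawn].sum())
                df[name] = comm
            df = df.loc[:, [c for c in df.columns]]
            rc = mb.rc_bray("x", "y", mb.CountTable(df.astype(np.int64)), n_null=199, seed=rep)
            abs_rc.append(abs(rc))
        assert np.mean(abs_rc) == pytest.approx(0.5, abs=0.1)

    def test_unknown_sample_rejected(self):
        rng = np.random.default_rng(9)
        table = mb.CountTable(self._pool_table(rng))
        with pytest.raises(mb.ParameterError):
            mb.rc_bray("s0", "nope", table, n_null=9, seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (3.1, None, "heterogeneous_selection"),
            (2.01, None, "heterogeneous_selection"),
            (-2.5, None, "homogeneous_selection"),
            (0.5, 0.99, "dispersal_limitation"),
            (0.5, -0.99, "homogenizing_dispersal"),
            (0.5, -0.2, "drift"),
            (2.0, 0.0, "drift"),  # boundary: strict > +2
            (-2.0, 0.0, "drift"),  # boundary: strict < -2
            (0.0, 0.95, "drift"),  # boundary: strict > +0.95
            (0.0, -0.95, "drift"),  # boundary: strict < -0.95
            (1.99, 0.951, "dispersal_limitation"),
            (-1.99, -0.951, "homogenizing_dispersal"),
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        assert mb.classify_pair(bnti, rc) == expected

    def test_missing_rc_rejected_inside_band(self):
        with pytest.raises(mb.ParameterError):
            mb.classify_pair(0.5, None)

    def test_undefined_bnti_rejected(self):
        with pytest.raises(mb.ParameterError):
            mb.classify_pair(float("nan"), 0.0)


class TestProcessFractions:
    def _results(self, labels, samples):
        pairs = list(itertools.combinations(samples, 2))
        return pd.DataFrame(
            {
                "sample_a": [p[0] for p in pairs],
                "sample_b": [p[1] for p in pairs],
                "bnti": 0.0,
                "rc_bray": 0.0,
                "process": labels[: len(pairs)],
            }
        )

    def test_all_drift(self):
        res = self._results(["drift"] * 6, ["a", "b", "c", "d"])
        out = mb.process_fractions(res)
        assert out.loc["all", "drift"] == pytest.approx(1.0)
        assert out.loc["all", [p for p in PROCESSES if p != "drift"]].sum() == 0.0

    def test_fractions_sum_to_one_and_match_tally(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(8)]
        labels = list(rng.choice(PROCESSES, size=28))
        res = self._results(labels, samples)
        strata = pd.Series(
            {s: ("upper" if i < 4 else "lower") for i, s in enumerate(samples)}
        )
        out = mb.process_fractions(res, strata=strata)
        for stratum in out.index:
            assert out.loc[stratum, list(PROCESSES)].sum() == pytest.approx(1.0)
        # brute-force tally for one stratum
        members = {s for s in samples if strata[s] == "upper"}
        sub = res[res["sample_a"].isin(members) & res["sample_b"].isin(members)]
        for proc in PROCESSES:
            assert out.loc["upper", proc] == pytest.approx(
                (sub["process"] == proc).mean()
            )

    def test_flagged_pairs_reported_separately(self):
        res = self._results(["drift"] * 5 + [None], ["a", "b", "c", "d"])
        out = mb.process_fractions(res)
        assert out.loc["all", "n_pairs"] == 5
        assert out.loc["all", "n_flagged"] == 1


class TestEndToEnd:
    def test_assembly_analysis_consistency(self):
        """Full stage on a small simulated table: labels respect thresholds
        and RC is only computed inside the |betaNTI| <= 2 band."""
        cfg = mb.scenario_config(
            "drift", n_taxa=40, n_stations=3, depth_layers=("5m", "3000m"),
            reads=500, generations=80, seed=21,
        )
        table, tree, *_ = mb.simulate_scenario(cfg)
        res, frac = mb.assembly_analysis(table, tree, n_null=99, seed=5)
        for row in res.itertuples():
            if np.isnan(row.bnti):
                assert row.process is None
                continue
            if abs(row.bnti) > 2:
                assert np.isnan(row.rc_bray)
            else:
                assert -1 <= row.rc_bray <= 1
            assert row.process == mb.classify_pair(
                row.bnti, None if np.isnan(row.rc_bray) else row.rc_bray
            )
        assert frac.loc["all", list(PROCESSES)].sum() == pytest.approx(1.0)
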