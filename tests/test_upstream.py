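"""Upstream kinase inference: sampling nulls, exact oracle, two-component
ranking, tree export."""

import numpy as np
import pandas as pd
import pytest

import kinomechip as kc
from kinomechip.errors import DegenerateNullError, SizeError, UnscorableError
from conftest import random_map, stats_from_lfcs


def _map_for(assignments, n_substrates, chip="PTK"):
    """Map from {kinase: [substrate indices]} over a panel of n substrates."""
    subs = [f"{chip}_{i + 1:03d}" for i in range(n_substrates)]
    fam = "TK" if chip == "PTK" else "AGC"
    kin_rows = [(k, fam) for k in assignments]
    edge_rows = [(k, subs[i], 1.0) for k, idxs in assignments.items() for i in idxs]
    covered = {s for _, s, _ in edge_rows}
    filler = []
    for s in subs:
        if s not in covered:
            filler.append(("FILLER", s, 1.0))
    if filler:
        kin_rows.append(("FILLER", fam))
        edge_rows += filler
    return kc.KinaseSubstrateMap(
        pd.DataFrame(kin_rows, columns=["kinase_id", "family_group"]),
        pd.DataFrame({"substrate_id": subs, "chip_type": chip}),
        pd.DataFrame(edge_rows, columns=["kinase_id", "substrate_id", "weight"]),
    )


def _panel_stats(lfcs, chip="PTK"):
    subs = [f"{chip}_{i + 1:03d}" for i in range(len(lfcs))]
    return stats_from_lfcs(pd.DataFrame({"pair1": lfcs}, index=subs), chip=chip)


class TestKinaseStatistic:
    def test_zero_lfcs_score_zero(self):
        amap = _map_for({"K1": [0, 1, 2]}, 6)
        stats = _panel_stats([0.0] * 6)
        assert kc.kinase_statistic(stats, amap, "K1") == 0.0

    def test_mean_of_mapped_lfcs(self):
        amap = _map_for({"K1": [0, 1]}, 4)
        stats = _panel_stats([0.4, 0.8, 5.0, -2.0])
        assert kc.kinase_statistic(stats, amap, "K1") == pytest.approx(0.6)

    def test_matches_independent_mean_on_seven_substrates(self):
        rng = np.random.default_rng(11)
        lfcs = rng.normal(0, 1, 20)
        idxs = list(rng.choice(20, size=7, replace=False))
        amap = _map_for({"K1": idxs}, 20)
        stats = _panel_stats(lfcs)
        assert kc.kinase_statistic(stats, amap, "K1") == pytest.approx(
            float(np.mean(lfcs[idxs])), abs=1e-12
        )

    def test_unmeasured_kinase_unscorable(self):
        amap = _map_for({"K1": [0]}, 2)
        stats = _panel_stats([0.1, 0.2])
        with pytest.raises(UnscorableError):
            kc.kinase_statistic(stats, amap, "MISSING")


class TestExhaustiveZ:
    def test_enumerated_example(self):
        """Panel (0,0,0,1), m=2 on the two zero substrates: null mean 0.25,
        sd 0.25, so z = −1 exactly."""
        amap = _map_for({"K1": [0, 1]}, 4)
        stats = _panel_stats([0.0, 0.0, 0.0, 1.0])
        res = kc.exhaustive_z(stats, amap, "K1", max_combinations=10)
        assert res.null_mean == pytest.approx(0.25)
        assert res.null_sd == pytest.approx(0.25)
        assert res.z == pytest.approx(-1.0)

    def test_m_equal_panel_is_size_error(self):
        amap = _map_for({"K1": [0, 1, 2]}, 3)
        stats = _panel_stats([0.1, 0.2, 0.3])
        with pytest.raises(SizeError):
            kc.exhaustive_z(stats, amap, "K1")

    def test_combination_bound_enforced(self):
        amap = _map_for({"K1": list(range(10))}, 30)
        stats = _panel_stats(list(np.random.default_rng(0).normal(size=30)))
        with pytest.raises(SizeError, match="exceeds"):
            kc.exhaustive_z(stats, amap, "K1", max_combinations=1000)

    def test_symmetric_panel_has_zero_null_mean(self):
        amap = _map_for({"K1": [0, 1]}, 6)
        stats = _panel_stats([-0.5, 0.5, -1.0, 1.0, -0.2, 0.2])
        res = kc.exhaustive_z(stats, amap, "K1")
        assert res.null_mean == pytest.approx(0.0, abs=1e-12)


class TestSamplingZ:
    def test_degenerate_panel_raises(self):
        amap = _map_for({"K1": [0, 1, 2]}, 6)
        stats = _panel_stats([0.7] * 6)
        with pytest.raises(DegenerateNullError):
            kc.sampling_z(stats, amap, "K1", seed=0)

    def test_converges_to_exhaustive(self):
        """m=2 over a 6-substrate panel: sampled z within 3/√n of exact."""
        rng = np.random.default_rng(4)
        lfcs = list(rng.normal(0, 1, 6))
        amap = _map_for({"K1": [0, 3]}, 6)
        stats = _panel_stats(lfcs)
        exact = kc.exhaustive_z(stats, amap, "K1")
        n_iter = 20000
        approx = kc.sampling_z(stats, amap, "K1", n_iter=n_iter, seed=1, min_substrates=2)
        assert abs(approx.z - exact.z) < 3 / np.sqrt(n_iter) * max(1.0, abs(exact.z)) + 0.05

    def test_statistic_at_null_mean_scores_near_zero(self):
        """A kinase whose substrates average to the panel mean gets z ≈ 0."""
        lfcs = [0.0, 1.0, 0.5, 0.5, 0.2, 0.8]  # panel mean 0.5
        amap = _map_for({"K1": [2, 3]}, 6)  # mapped mean exactly 0.5
        stats = _panel_stats(lfcs)
        res = kc.sampling_z(stats, amap, "K1", n_iter=20000, seed=0, min_substrates=2)
        assert abs(res.z) < 0.05

    def test_min_substrates_enforced(self):
        amap = _map_for({"K1": [0, 1]}, 6)
        stats = _panel_stats([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        with pytest.raises(UnscorableError):
            kc.sampling_z(stats, amap, "K1", seed=0, min_substrates=3)

    def test_score_table_shares_nulls_consistently(self):
        rng = np.random.default_rng(7)
        amap = random_map(rng, n_substrates=40, n_kinases=6)
        lfcs = pd.DataFrame(
            {"p1": rng.normal(0, 0.5, 40)}, index=[f"PTK_{i + 1:03d}" for i in range(40)]
        )
        stats = stats_from_lfcs(lfcs)
        table = kc.score_kinases_z(stats, amap, n_iter=5000, seed=0)
        assert len(table) > 0
        assert set(table.columns) >= {"kinase_id", "chip_type", "m", "stat", "z"}
        # z must standardize the stat: recompute one kinase directly
        row = table.iloc[0]
        single = kc.sampling_z(stats, amap, row["kinase_id"], n_iter=50000, seed=3)
        assert abs(single.z - row["z"]) < 0.2


class TestUkaRank:
    def _spiked(self, seed, n_substrates=60, n_kinases=12, m=6, shift=1.0, sd=0.1, n_pairs=5):
        rng = np.random.default_rng(seed)
        amap = random_map(rng, n_substrates=n_substrates, n_kinases=n_kinases, m_range=(3, 8))
        spiked_subs = rng.choice(n_substrates, size=m, replace=False)
        extra = _map_for({"SPIKED": list(spiked_subs)}, n_substrates)
        kin = pd.concat([amap.kinases, extra.kinases.iloc[[0]]], ignore_index=True)
        edges = pd.concat(
            [amap.edges, extra.edges[extra.edges["kinase_id"] == "SPIKED"]], ignore_index=True
        )
        amap = kc.KinaseSubstrateMap(kin, amap.substrates, edges)
        lfc = rng.normal(0, sd, (n_substrates, n_pairs))
        lfc[spiked_subs, :] += shift
        subs = [f"PTK_{i + 1:03d}" for i in range(n_substrates)]
        stats = stats_from_lfcs(pd.DataFrame(lfc, index=subs, columns=[f"p{i}" for i in range(n_pairs)]))
        return amap, stats

    def test_spiked_kinase_ranks_first(self):
        for seed in range(5):
            amap, stats = self._spiked(seed)
            table = kc.uka_rank(stats, amap, n_perm=300, n_iter=1000, seed=seed)
            assert table.iloc[0]["kinase_id"] == "SPIKED"
            assert table.iloc[0]["rank"] == 1

    def test_all_zero_lfcs_give_zero_scores(self):
        amap = _map_for({"K1": [0, 1, 2], "K2": [3, 4, 5]}, 8)
        subs = [f"PTK_{i + 1:03d}" for i in range(8)]
        stats = stats_from_lfcs(pd.DataFrame(np.zeros((8, 3)), index=subs, columns=list("abc")))
        table = kc.uka_rank(stats, amap, n_perm=200, seed=0)
        assert (table["final_score"] == 0).all()

    def test_sign_flip_antisymmetry(self):
        amap, stats = self._spiked(3)
        fwd = kc.uka_rank(stats, amap, n_perm=300, n_iter=1000, seed=9)
        neg = kc.SubstrateStats(-stats.per_pair, stats.chip, stats.contrast, stats.threshold)
        rev = kc.uka_rank(neg, amap, n_perm=300, n_iter=1000, seed=9)
        merged = fwd.merge(rev, on="kinase_id", suffixes=("_f", "_r"))
        np.testing.assert_allclose(
            merged["final_score_f"].to_numpy(), -merged["final_score_r"].to_numpy(), atol=1e-9
        )
        assert list(fwd["kinase_id"]) == list(rev["kinase_id"])  # |rank| order preserved

    def test_row_shuffle_changes_no_score(self):
        amap, stats = self._spiked(5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(stats.per_pair))
        shuffled = kc.SubstrateStats(
            stats.per_pair.iloc[perm], stats.chip, stats.contrast, stats.threshold
        )
        a = kc.uka_rank(stats, amap, n_perm=200, n_iter=500, seed=4)
        b = kc.uka_rank(shuffled, amap, n_perm=200, n_iter=500, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_small_n_perm_warns(self):
        amap, stats = self._spiked(1)
        with pytest.warns(UserWarning, match="n_perm"):
            kc.uka_rank(stats, amap, n_perm=50, n_iter=200, seed=0)


class TestNullCalibration:
    def test_false_positive_rate_near_nominal(self):
        """i.i.d. N(0,σ²) LFCs with random maps: ~5% of kinases exceed |z|>1.96."""
        rng = np.random.default_rng(123)
        n_hits = 0
        n_total = 0
        for batch in range(6):
            amap = random_map(rng, n_substrates=80, n_kinases=60, m_range=(3, 12))
            lfcs = pd.DataFrame(
                {"p1": rng.normal(0, 0.4, 80)}, index=[f"PTK_{i + 1:03d}" for i in range(80)]
            )
            table = kc.score_kinases_z(stats_from_lfcs(lfcs), amap, n_iter=2000, seed=batch)
            z = table["z"].dropna()
            n_hits += int((z.abs() > 1.96).sum())
            n_total += len(z)
        rate = n_hits / n_total
        assert 0.02 <= rate <= 0.09


class TestTreeExport:
    def test_table_complete_and_signed(self):
        scores = pd.DataFrame(
            {
                "kinase_id": ["K1", "K2", "K3"],
                "family_group": ["TK", "TK", "AGC"],
                "stat": [0.5, -0.2, 0.1],
                "final_score": [2.0, -1.0, 0.3],
            }
        )
        tree = kc.kinome_tree_export(scores)
        assert list(tree.columns) == ["kinase_id", "family_group", "activity", "significance"]
        assert len(tree) == 3
        assert (tree.loc[tree["activity"] > 0, "activity"] > 0).all()
        assert (tree["significance"] >= 0).all()
        assert tree.loc[0, "activity"] == 0.5

    def test_round_trip(self, tmp_path):
        scores = pd.DataFrame(
            {"kinase_id": ["K1", "K2"], "family_group": ["TK", "CK1"], "stat": [0.25, -0.125],
             "z": [1.5, -2.25]}
        )
        tree = kc.kinome_tree_export(scores)
        path = tmp_path / "tree.tsv"
        from kinomechip.upstream import read_tree_tsv, write_tree_tsv

        write_tree_tsv(tree, path)
        back = read_tree_tsv(path)
        pd.testing.assert_frame_equal(back, tree)
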