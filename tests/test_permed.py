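"""PerMed scoring and the clinical-trial-on-a-chip report."""

import numpy as np
import pandas as pd
import pytest

import kinomechip as kc
from kinomechip.errors import ContrastError, InvalidParameterError, UnscorableError
from kinomechip.permed import DrugResult
from conftest import make_matrix


def _contrast_matrix(ctrl, treat, kinase_map=None):
    """Linear matrix with vehicle/drug columns and a map over all substrates."""
    subs = [f"PTK_{i + 1:03d}" for i in range(len(ctrl))]
    values = pd.DataFrame(
        {("P1", "tumor", "vehicle"): ctrl, ("P1", "tumor", "imatinib"): treat}, index=subs
    )
    mat = make_matrix(values)
    if kinase_map is None:
        kin = pd.DataFrame({"kinase_id": ["K1"], "family_group": ["TK"]})
        edges = pd.DataFrame({"kinase_id": "K1", "substrate_id": subs, "weight": 1.0})
        sub_df = pd.DataFrame({"substrate_id": subs, "chip_type": "PTK"})
        kinase_map = kc.KinaseSubstrateMap(kin, sub_df, edges)
    return mat, kinase_map


class TestPerMedScore:
    def test_identical_conditions_score_zero(self):
        mat, amap = _contrast_matrix([10.0, 20.0], [10.0, 20.0])
        rep = kc.permed_score(mat, amap, "K1", "imatinib", "vehicle")
        assert rep.score == 0.0

    def test_hand_computed_mixture(self):
        """Percent changes (−50, −50, +50) average to −16.667%."""
        mat, amap = _contrast_matrix([10.0, 20.0, 40.0], [5.0, 10.0, 60.0])
        rep = kc.permed_score(mat, amap, "K1", "imatinib", "vehicle")
        assert rep.score == pytest.approx(-100 / 6, abs=1e-9)
        assert rep.n_substrates == 3

    def test_scores_below_minus_hundred_are_legal(self):
        """Background-subtracted treated signal below zero: −400%."""
        mat, amap = _contrast_matrix([10.0], [-30.0])
        rep = kc.permed_score(mat, amap, "K1", "imatinib", "vehicle")
        assert rep.score == pytest.approx(-400.0, abs=1e-9)

    def test_near_zero_control_excluded_and_reported(self):
        mat, amap = _contrast_matrix([10.0, 1e-6], [5.0, 4.0])
        rep = kc.permed_score(mat, amap, "K1", "imatinib", "vehicle", epsilon=1e-3)
        assert rep.score == pytest.approx(-50.0)
        assert "PTK_002" in rep.excluded
        assert "epsilon" in rep.excluded["PTK_002"]

    def test_all_excluded_is_unscorable(self):
        mat, amap = _contrast_matrix([1e-9, 1e-9], [1.0, 1.0])
        with pytest.raises(UnscorableError):
            kc.permed_score(mat, amap, "K1", "imatinib", "vehicle")

    def test_requires_linear_scale(self):
        mat, amap = _contrast_matrix([10.0], [5.0])
        mat.transform = "log2"
        with pytest.raises(InvalidParameterError):
            kc.permed_score(mat, amap, "K1", "imatinib", "vehicle")

    def test_missing_label_is_contrast_error(self):
        mat, amap = _contrast_matrix([10.0], [5.0])
        with pytest.raises(ContrastError):
            kc.permed_score(mat, amap, "K1", "rebastinib", "vehicle")

    def test_uniform_gain_leaves_score_unchanged(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(5, 50, 8)
        treat = ctrl * rng.uniform(0.2, 1.5, 8)
        mat1, amap = _contrast_matrix(ctrl, treat)
        mat2, _ = _contrast_matrix(ctrl * 7.5, treat * 7.5)
        a = kc.permed_score(mat1, amap, "K1", "imatinib", "vehicle").score
        b = kc.permed_score(mat2, amap, "K1", "imatinib", "vehicle").score
        assert a == pytest.approx(b, rel=1e-12)


class TestOracleEquivalence:
    def test_pipeline_equals_analytic_truth_on_noiseless_toy(
        self, toy_design, toy_map, toy_truth, toy_cohort, toy_panel
    ):
        raw = kc.simulate_signals(toy_design, toy_map, toy_truth, toy_cohort, toy_panel, seed=0)
        mat = kc.quantify(raw, toy_design)
        rep = kc.permed_score(mat, toy_map, "ABL1", "imatinib", "vehicle")
        truth_val = kc.truth_permed(
            toy_map, toy_truth, toy_panel, "ABL1", "imatinib", sex="M", members=["P1"]
        )
        assert abs(rep.score - truth_val) < 1e-9

    def test_target_dose_at_ic50_gives_exactly_minus_fifty(
        self, toy_design, toy_map, toy_truth, toy_cohort, toy_panel
    ):
        raw = kc.simulate_signals(toy_design, toy_map, toy_truth, toy_cohort, toy_panel, seed=0)
        mat = kc.quantify(raw, toy_design)
        rep = kc.permed_score(mat, toy_map, "ABL1", "imatinib", "vehicle")
        assert rep.score == pytest.approx(-50.0, abs=1e-9)


class TestOffTargetDetection:
    def test_zero_scores_give_empty_list(self):
        assert kc.detect_off_target({"A": 0.0, "B": 0.0, "T": 0.0}, "T") == []

    def test_filter_excludes_target_and_sorts_by_magnitude(self):
        scores = {"A": -30.0, "B": 25.0, "T": -80.0}
        hits = kc.detect_off_target(scores, "T", threshold=20)
        assert hits == [("A", -30.0), ("B", 25.0)]

    def test_high_threshold_empties_list(self):
        scores = {"A": -30.0, "B": 25.0, "T": -80.0}
        assert kc.detect_off_target(scores, "T", threshold=100) == []

    def test_direction_retained_for_compensatory_increases(self):
        hits = kc.detect_off_target({"ERK1": 45.0, "T": -60.0}, "T")
        assert hits == [("ERK1", 45.0)]


class TestRankDrugs:
    def _result(self, drug, target, off=(), non_resp=False, assayed=True):
        return DrugResult(drug, "T", target, list(off), non_resp, {}, assayed)

    def test_most_negative_target_first(self):
        order = kc.rank_drugs(
            [self._result("a", -300.0), self._result("b", -45.0), self._result("c", -260.0)]
        )
        assert order == ["a", "c", "b"]

    def test_fewer_off_targets_break_ties(self):
        a = self._result("a", -100.0, off=[("X", 30.0)] * 3)
        b = self._result("b", -100.0, off=[])
        assert kc.rank_drugs([a, b]) == ["b", "a"]

    def test_non_responder_ranked_last(self):
        best = self._result("best_but_nr", 10.0, non_resp=True)
        ok = self._result("ok", -20.0)
        assert kc.rank_drugs([best, ok]) == ["ok", "best_but_nr"]

    def test_not_assayed_ranked_after_everything(self):
        na = self._result("na", None, assayed=False)
        nr = self._result("nr", 5.0, non_resp=True)
        ok = self._result("ok", -5.0)
        assert kc.rank_drugs([na, nr, ok]) == ["ok", "nr", "na"]


class TestRunTrial:
    def _trial_setup(self, non_responders=()):
        amap = kc.build_default_annotation(0)
        cohort = kc.CohortDesign(
            patients=(("P1", "M"), ("P2", "F")), tissues=("tumor",), technical_replicates=1
        )
        panel = kc.DrugPanel()
        design = kc.AssayDesign(
            cycles_per_chip={"PTK": 12, "STK": 14}, exposure_times=(10.0, 50.0, 200.0)
        )
        truth = kc.default_ground_truth(
            amap, cohort, panel, seed=0, noise=kc.NOISELESS, non_responders=dict(non_responders)
        )
        raw = kc.simulate_signals(design, amap, truth, cohort, panel, seed=0)
        mat = kc.quantify(raw, design)
        return mat, amap, panel, truth

    def test_target_and_off_target_calls_on_noiseless_run(self):
        mat, amap, panel, truth = self._trial_setup()
        reports = kc.run_trial(mat, amap, panel, kc.TrialParams(min_substrates=3))
        assert len(reports) == 2
        rep = next(r for r in reports if r.unit[0] == "P1")
        ima = rep.drugs["imatinib"]
        # ABL1 inhibited; dilution by co-mapped uninhibited kinases keeps the
        # observed score above the exclusive-substrate occupancy bound (−62.5%)
        assert -62.5 < ima.target_permed < -10
        assert ima.non_responder is False
        # ABL2 carries its own IC50 for every panel drug and is not the
        # nominal target, so it must surface as an off-target call
        reb = rep.drugs["rebastinib"]
        assert any(k == "ABL2" for k, _ in reb.off_targets)
        assert len(rep.drugs["olverembatinib"].off_targets) >= len(ima.off_targets)
        assert set(rep.drug_ranking) == {"imatinib", "rebastinib", "olverembatinib"}
        # stronger ABL inhibitors outrank imatinib on-target
        assert rep.drug_ranking.index("imatinib") == 2

    def test_non_responder_fixture_flags_patient(self):
        mat, amap, panel, truth = self._trial_setup(
            non_responders={("P2", "imatinib"): "ABL1"}
        )
        reports = kc.run_trial(mat, amap, panel, kc.TrialParams(min_substrates=3))
        by_unit = {r.unit[0]: r for r in reports}
        assert by_unit["P2"].drugs["imatinib"].non_responder is True
        assert by_unit["P1"].drugs["imatinib"].non_responder is False
        assert by_unit["P2"].drug_ranking[-1] == "imatinib"

    def test_missing_vehicle_is_contrast_error(self):
        subs = ["PTK_001"]
        values = pd.DataFrame({("P1", "tumor", "imatinib"): [5.0]}, index=subs)
        mat = make_matrix(values)
        kin = pd.DataFrame({"kinase_id": ["K1"], "family_group": ["TK"]})
        sub_df = pd.DataFrame({"substrate_id": subs, "chip_type": "PTK"})
        edges = pd.DataFrame({"kinase_id": ["K1"], "substrate_id": subs, "weight": [1.0]})
        amap = kc.KinaseSubstrateMap(kin, sub_df, edges)
        panel = kc.DrugPanel(drugs=(kc.Drug("imatinib", "K1", 1000.0),))
        with pytest.raises(ContrastError, match="vehicle"):
            kc.run_trial(mat, amap, panel)

    def test_absent_drug_listed_not_assayed(self):
        subs = ["PTK_001"]
        values = pd.DataFrame(
            {("P1", "tumor", "vehicle"): [10.0], ("P1", "tumor", "imatinib"): [5.0]}, index=subs
        )
        mat = make_matrix(values)
        kin = pd.DataFrame({"kinase_id": ["K1"], "family_group": ["TK"]})
        sub_df = pd.DataFrame({"substrate_id": subs, "chip_type": "PTK"})
        edges = pd.DataFrame({"kinase_id": ["K1"], "substrate_id": subs, "weight": [1.0]})
        amap = kc.KinaseSubstrateMap(kin, sub_df, edges)
        panel = kc.DrugPanel(
            drugs=(kc.Drug("imatinib", "K1", 1000.0), kc.Drug("rebastinib", "K1", 100.0))
        )
        reports = kc.run_trial(mat, amap, panel)
        assert reports[0].drugs["rebastinib"].assayed is False
        assert reports[0].drug_ranking[-1] == "rebastinib"

    def test_report_serialization_round_trip(self, tmp_path):
        mat, amap, panel, _ = self._trial_setup()
        reports = kc.run_trial(mat, amap, panel, kc.TrialParams(min_substrates=3))
        from kinomechip.permed import write_trial_json, write_trial_tsv
        import json

        write_trial_json(reports, tmp_path / "trial.json")
        write_trial_tsv(reports, tmp_path / "trial.tsv")
        payload = json.loads((tmp_path / "trial.json").read_text())
        assert len(payload) == 2
        assert payload[0]["drugs"]["imatinib"]["nominal_target"] == "ABL1"
        table = pd.read_csv(tmp_path / "trial.tsv", sep="\t")
        assert {"patient_id", "drug_id", "kinase_id", "permed_pct"} <= set(table.columns)
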