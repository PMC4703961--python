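"""Statistical ladder: calibration, power, calls, concordance."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from omiflim import endpoints as ep
from omiflim import stats as st
from omiflim import synthetic as syn
from omiflim.reference import reference_calls_72hr


class TestNormality:
    def test_rejects_skewed_sample(self):
        rng = np.random.default_rng(0)
        hits = sum(st.test_normality(rng.exponential(1.0, 500))[1] < 1e-3
                   for _ in range(50))
        assert hits >= 48

    def test_accepts_most_normal_samples(self):
        rng = np.random.default_rng(1)
        rejections = sum(st.test_normality(rng.normal(0, 1, 500))[1] < 0.05
                         for _ in range(100))
        assert rejections <= 12

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 20"):
            st.test_normality(np.arange(10.0))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.test_normality(np.full(100, 3.0))


class TestKruskalDunn:
    def test_identical_constant_groups(self):
        groups = {"a": np.full(5, 2.0), "b": np.full(6, 2.0)}
        res = st.compare_morphology_groups(groups)
        assert len(res) == 1  # no post-hoc rows
        row = res.iloc[0]
        assert row["statistic"] == 0.0 and row["p_raw"] == 1.0

    def test_shifted_group_detected(self):
        # one of three groups shifted by 2 SD: Dunn flags it with good power
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            groups = {"a": rng.normal(0, 1, 9), "b": rng.normal(0, 1, 9),
                      "c": rng.normal(2, 1, 9)}
            res = st.compare_morphology_groups(groups)
            dunn = res[res["test"] == "dunn"]
            sig = dunn[(dunn["p_adjusted"] < 0.05)
                       & (dunn["group"].eq("c") | dunn["comparator"].eq("c"))]
            hits += len(sig) > 0
        assert hits >= 80

    def test_bonferroni_adjustment_rule(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(i, 1, 15) for i, g in enumerate("abcd")}
        dunn = st.dunn_posthoc(groups)
        m = len(dunn)
        assert m == 6
        assert np.allclose(dunn["p_adjusted"],
                           np.minimum(1.0, m * dunn["p_raw"]))
        assert dunn["p_adjusted"].between(0, 1).all()

    def test_requires_group_sizes(self):
        with pytest.raises(ValueError, match="n >= 3"):
            st.compare_morphology_groups({"a": np.arange(2.0),
                                          "b": np.arange(5.0)})


class TestControlFlim:
    def test_identical_samples_not_called(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.9, 0.15, 100)
        fresh = pd.DataFrame({"nadh_tau_m": x})
        res = st.compare_control_flim(fresh, fresh.copy(), ["nadh_tau_m"])
        assert res["direction"].iloc[0] == "none"
        assert res["p_adjusted"].iloc[0] > 0.99

    def test_lifetime_shift_detected_with_power(self):
        # -0.1 ns shift on SD 0.15 at n=200/group
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            fresh = pd.DataFrame({"nadh_tau_m": rng.normal(0.9, 0.15, 200),
                                  "fad_tau_m": rng.normal(1.3, 0.2, 200)})
            frozen = pd.DataFrame({"nadh_tau_m": rng.normal(0.8, 0.15, 200),
                                   "fad_tau_m": rng.normal(1.3, 0.2, 200)})
            res = st.compare_control_flim(fresh, frozen,
                                          ["nadh_tau_m", "fad_tau_m"])
            row = res[res["endpoint"] == "nadh_tau_m"].iloc[0]
            hits += row["direction"] == "decrease"
        assert hits >= 18

    def test_bonferroni_familywise_control(self):
        rng = np.random.default_rng(6)
        fwer = 0
        for _ in range(200):
            fresh = pd.DataFrame({"a": rng.normal(0, 1, 40),
                                  "b": rng.normal(0, 1, 40)})
            frozen = pd.DataFrame({"a": rng.normal(0, 1, 40),
                                   "b": rng.normal(0, 1, 40)})
            res = st.compare_control_flim(fresh, frozen, ["a", "b"], min_n=30)
            fwer += (res["p_adjusted"] < 0.05).any()
        assert fwer / 200 <= 0.07
        assert (res["p_adjusted"] >= res["p_raw"]).all()

    def test_small_groups_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="n="):
            st.compare_control_flim(df, df, ["a"])


class TestTukeyCaller:
    def test_matches_statsmodels_tukey(self):
        # independent oracle: statsmodels' studentized-range implementation
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 200)
        grp = rng.choice(["control", "a", "b", "c"], 200)
        mine = {g: p for g, _, p in st.tukey_vs_control(vals, grp, "control")}
        tuk = pairwise_tukeyhsd(vals, grp)
        ref = pd.DataFrame(tuk.summary().data[1:],
                           columns=tuk.summary().data[0])
        for _, r in ref.iterrows():
            if "control" not in (str(r["group1"]), str(r["group2"])):
                continue
            other = str(r["group2"]) if str(r["group1"]) == "control" \
                else str(r["group1"])
            assert mine[other] == pytest.approx(float(r["p-adj"]), abs=2e-3)

    def test_identical_treatment_called_none(self):
        rng = np.random.default_rng(8)
        rows = [pd.DataFrame({"treatment": tr, "timepoint_hr": tp,
                              "omi_index": rng.normal(0, 1, 40)})
                for tr in ("control", "drug") for tp in (24, 48, 72)]
        _, calls = st.drug_response_timecourse(pd.concat(rows,
                                                         ignore_index=True))
        assert set(calls["call"]) == {"none"}

    def test_effect_at_72hr_only(self):
        # OMI decrease induced only at 72 h is called there and nowhere else
        design = syn.ExperimentDesign(
            samples=("S1",), preparations=("fresh",),
            treatments=("control", "drug_A"),
            effects={("S1", "fresh", "drug_A", 72): (-1.0, -1.0, 1.0)},
            seed=21)
        cells = ep.omi_index(syn.generate_experiment(design).cells)
        _, calls = st.drug_response_timecourse(cells)
        got = calls.set_index("timepoint_hr")["call"]
        assert got.loc[24] == "none" and got.loc[48] == "none"
        assert got.loc[72] == "decrease"

    def test_row_order_does_not_change_calls(self):
        design = syn.ExperimentDesign(
            samples=("S1",), preparations=("fresh",),
            effects={("S1", "fresh", "drug_B", 48): (-1.0, -1.0, 1.0)},
            seed=22)
        cells = ep.omi_index(syn.generate_experiment(design).cells)
        _, a = st.drug_response_timecourse(cells)
        shuffled = cells.sample(frac=1.0, random_state=0)
        _, b = st.drug_response_timecourse(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_design_cell_reported(self):
        rng = np.random.default_rng(9)
        rows = [pd.DataFrame({"treatment": "control", "timepoint_hr": tp,
                              "omi_index": rng.normal(0, 1, 10)})
                for tp in (24, 48)]
        rows.append(pd.DataFrame({"treatment": "drug", "timepoint_hr": 24,
                                  "omi_index": rng.normal(0, 1, 10)}))
        with pytest.raises(ValueError, match="drug.*48"):
            st.drug_response_timecourse(pd.concat(rows, ignore_index=True))


class TestConcordance:
    def test_published_worked_example(self):
        # six 7-day frozen preparations vs fresh at 72 h: 4 of 24 calls
        # discordant (~16%)
        fresh, frozen = reference_calls_72hr()
        conc = st.concordance(fresh, frozen)
        assert conc.n_total == 24
        assert conc.n_discordant == 4
        assert conc.inconsistency_fraction == pytest.approx(4 / 24)

    def test_identical_and_opposed_call_sets(self):
        fresh, frozen = reference_calls_72hr()
        as_frozen = fresh.assign(preparation="flash_frozen", recovery_days=7)
        assert st.concordance(fresh, as_frozen).n_discordant == 0
        flipped = as_frozen.assign(
            call=as_frozen["call"].map({"decrease": "increase",
                                        "increase": "decrease",
                                        "none": "decrease"}))
        conc = st.concordance(fresh, flipped)
        assert conc.n_discordant == conc.n_total == len(flipped)

    def test_label_swap_symmetry(self):
        fresh, frozen = reference_calls_72hr()
        one_prep = frozen[frozen["preparation"] == "flash_frozen"]
        fresh_sub = fresh[fresh["sample"].isin(one_prep["sample"])]
        fwd = st.concordance(fresh_sub, one_prep)
        rev = st.concordance(
            one_prep.drop(columns=["preparation", "recovery_days"]),
            fresh_sub)
        assert fwd.n_discordant == rev.n_discordant

    def test_unmatched_keys_skipped(self):
        fresh, frozen = reference_calls_72hr()
        extra = pd.concat([frozen, pd.DataFrame([{
            "sample": "PatientX", "preparation": "flash_frozen",
            "recovery_days": 7, "treatment": "combo", "timepoint_hr": 72,
            "call": "none"}])], ignore_index=True)
        conc = st.concordance(fresh, extra)
        assert conc.n_total == 24


class TestSpearmanAndStaining:
    def test_rank_correlation_limits(self):
        x = np.arange(8.0)
        assert st.correlate_fresh_frozen(x, 2 * x + 1)[0] == 1.0
        assert st.correlate_fresh_frozen(x, -x)[0] == -1.0

    def test_shared_effects_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(50):
            signal = rng.normal(0, 1, 12)
            fresh = signal + rng.normal(0, 0.4, 12)
            frozen = signal + rng.normal(0, 0.4, 12)
            rho, p = st.correlate_fresh_frozen(fresh, frozen)
            hits += (rho > 0) and (p < 0.05)
        assert hits >= 40

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.correlate_fresh_frozen(np.ones(8), np.arange(8.0))
        with pytest.raises(ValueError):
            st.correlate_fresh_frozen(np.arange(4.0), np.arange(4.0))

    def test_positive_percentages(self):
        table = pd.DataFrame({
            "organoid_id": [1] * 12 + [2] * 10,
            "positive": [True] * 3 + [False] * 9 + [False] * 10,
        })
        per_org, _ = st.positive_fraction(table)
        got = per_org.set_index("organoid_id")["percent_positive"]
        assert got.loc[1] == pytest.approx(25.0)
        assert got.loc[2] == 0.0

    def test_group_difference_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(30):
            rows = []
            for g, rate in (("ctrl", 0.10), ("drug", 0.60)):
                for org in range(6):
                    rows.append(pd.DataFrame({
                        "group": g, "organoid_id": f"{g}{org}",
                        "positive": rng.random(40) < rate}))
            per_org, tests = st.positive_fraction(
                pd.concat(rows, ignore_index=True), group_col="group")
            assert tests is not None
            hits += (tests.iloc[0]["p_raw"] < 0.05)
        assert hits >= 27
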