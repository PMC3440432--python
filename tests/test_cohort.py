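"""Cohort pipeline: filters, unit conversion, orchestration, summaries, envelopes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from thrombogen.cohort import (
    CohortTable,
    EXCLUSION_COLUMNS,
    FACTOR_COLUMNS,
    apply_inclusion_filters,
    envelope_curves,
    molar_to_percent,
    percent_to_molar,
    read_cohort,
    run_cohort,
    summarize_groups,
)
from thrombogen.kinetics import PHYSIOLOGIC_MEAN, SimulationConfig
from thrombogen.synthetic import CohortDesign, generate_cohort

r = dataclasses.replace


def make_table(n, flag_sets=None):
    rows = []
    for i in range(n):
        rec = {
            "subject_id": f"X{i:03d}",
            "fII_uM": 1.4, "fV_nM": 20.0, "fVII_nM": 10.0, "fVIII_nM": 0.7,
            "fIX_nM": 90.0, "fX_nM": 160.0, "AT_uM": 3.6, "TFPI_nM": 2.5, "PC_nM": 65.0,
            "sex": "F", "age": 40.0, "pc_mutation": "no", "pt_g20210a": "no",
            "thrombosis_history": "none",
            **{c: False for c in EXCLUSION_COLUMNS},
        }
        if flag_sets and i in flag_sets:
            for col in flag_sets[i]:
                rec[col] = True
        rows.append(rec)
    return CohortTable(pd.DataFrame(rows))


class TestFilters:
    def test_printed_counts_give_364(self):
        table = generate_cohort(raw_roster=True)
        assert len(table) == 514
        filtered = apply_inclusion_filters(table)
        assert len(filtered) == 364
        assert filtered.filter_report.removed_by_category == {
            "coumadin": 35, "unknown_coumadin": 5, "unconfirmed_thrombosis": 11,
            "superficial_only": 18, "insufficient_sample": 6, "insufficient_composition": 75,
        }
        assert not filtered.df[list(EXCLUSION_COLUMNS)].any().any()

    def test_no_flags_identity(self):
        table = make_table(10)
        out = apply_inclusion_filters(table)
        assert len(out) == 10
        assert out.filter_report.n_removed == 0

    def test_double_flag_removed_once(self):
        table = make_table(5, {2: ["excl_coumadin", "excl_insufficient_sample"]})
        out = apply_inclusion_filters(table)
        assert len(out) == 4
        assert out.filter_report.n_removed == 1
        assert out.filter_report.removed_by_category["coumadin"] == 1
        assert out.filter_report.removed_by_category["insufficient_sample"] == 1

    def test_missing_flag_column_raises(self):
        table = make_table(3)
        table.df.drop(columns=["excl_coumadin"], inplace=True)
        with pytest.raises(ValueError, match="excl_coumadin"):
            apply_inclusion_filters(table)

    def test_union_arithmetic(self):
        table = make_table(20, {1: ["excl_coumadin"], 2: ["excl_coumadin", "excl_superficial_only"],
                                3: ["excl_insufficient_sample"]})
        out = apply_inclusion_filters(table)
        assert out.filter_report.n_retained == 20 - 3
        assert sum(out.filter_report.removed_by_category.values()) == 4  # occurrences


class TestUnitConversion:
    def test_hundred_percent_is_mean(self):
        out = percent_to_molar({c: 100.0 for c in FACTOR_COLUMNS})
        for c in FACTOR_COLUMNS:
            assert out[c] == pytest.approx(getattr(PHYSIOLOGIC_MEAN, c))

    def test_fviii_150_percent(self):
        assert percent_to_molar({"fVIII": 150.0})["fVIII_nM"] == pytest.approx(1.05)

    def test_pc_72_percent_matches_carrier_mean(self):
        assert percent_to_molar({"PC": 72.0})["PC_nM"] == pytest.approx(46.8)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        pct = {c: rng.uniform(40, 180) for c in FACTOR_COLUMNS}
        molar = percent_to_molar(pct)
        back = molar_to_percent(molar)
        for c in FACTOR_COLUMNS:
            assert back[c] == pytest.approx(pct[c], rel=1e-12)

    def test_nonpositive_percent_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            percent_to_molar({"fII_uM": 0.0})

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            percent_to_molar({"fXIII": 100.0})

    def test_read_percent_dialect(self, tmp_path):
        df = pd.DataFrame(
            {
                "subject_id": ["a"],
                **{f"{c.rsplit('_', 1)[0]}_pct": [100.0] for c in FACTOR_COLUMNS},
            }
        )
        p = tmp_path / "pct.csv"
        df.to_csv(p, index=False)
        table = read_cohort(p)
        assert table.df.loc[0, "fII_uM"] == pytest.approx(1.4)

    def test_mixed_dialect_rejected(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["a"], "fII_uM": [1.4], "fV_pct": [100.0]})
        p = tmp_path / "mixed.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="mixed"):
            read_cohort(p)

    def test_duplicate_subject_rejected(self, tmp_path):
        table = make_table(2)
        table.df.loc[1, "subject_id"] = table.df.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="duplicate subject_id"):
            CohortTable(table.df)


@pytest.fixture(scope="module")
def small_run(model):
    table = make_table(3)
    table.df.loc[0, "PC_nM"] = 47.0
    table.df.loc[1, "PC_nM"] = 110.0
    metrics, traces = run_cohort(table, model, SimulationConfig(), keep_traces=True)
    return table, metrics, traces


class TestRunCohort:
    def test_shape_contract(self, small_run):
        _, metrics, _ = small_run
        assert len(metrics) == 3 * 2 + 2  # subjects x pathways + control per pathway
        assert metrics["is_control"].sum() == 2

    def test_pc_low_more_procoagulant(self, small_run):
        _, metrics, _ = small_run
        with_pc = metrics.query("pathway == 'with_pc' and not is_control").set_index("subject_id")
        assert with_pc.loc["X000", "MaxL_nM"] > with_pc.loc["X001", "MaxL_nM"]
        assert with_pc.loc["X000", "AUC_uM_s"] > with_pc.loc["X001", "AUC_uM_s"]

    def test_without_pc_at_least_with_pc(self, small_run):
        _, metrics, _ = small_run
        m = metrics[~metrics.is_control].pivot(index="subject_id", columns="pathway")
        assert (m[("MaxL_nM", "without_pc")] >= m[("MaxL_nM", "with_pc")]).all()
        assert (m[("AUC_uM_s", "without_pc")] >= m[("AUC_uM_s", "with_pc")]).all()

    def test_exceeds_flags_against_same_arm_control(self, small_run):
        _, metrics, _ = small_run
        ctrl = metrics[metrics.is_control].set_index("pathway")
        row = metrics.query("subject_id == 'X000' and pathway == 'with_pc'").iloc[0]
        assert row["exceeds_MaxL"] == (row["MaxL_nM"] > ctrl.loc["with_pc", "MaxL_nM"])


class TestSummaries:
    def test_hand_built_moments(self):
        table = make_table(3)
        metrics = pd.DataFrame(
            {
                "subject_id": ["X000", "X001", "X002"],
                "pathway": ["with_pc"] * 3,
                "MaxL_nM": [10.0, 20.0, 30.0],
                "TMaxL_s": [1.0] * 3, "MaxR_nM_per_s": [1.0] * 3, "TMaxR_s": [1.0] * 3,
                "AUC_uM_s": [1.0] * 3, "CT_s": [1.0] * 3,
                "is_control": [False] * 3,
            }
        )
        out = summarize_groups(metrics, table, "pc_mutation", metrics=("MaxL_nM",))
        row = out[(out.stratum == "all")].iloc[0]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(20.0)
        assert row["sd"] == pytest.approx(10.0)

    def test_group_sizes_from_design(self):
        table = generate_cohort(CohortDesign(seed=5))
        fake = pd.DataFrame(
            {
                "subject_id": table.df.subject_id,
                "pathway": "with_pc",
                "MaxL_nM": 1.0, "TMaxL_s": 1.0, "MaxR_nM_per_s": 1.0,
                "TMaxR_s": 1.0, "AUC_uM_s": 1.0, "CT_s": 1.0,
                "is_control": False,
            }
        )
        out = summarize_groups(fake, table, "pc_mutation", by_sex=True, metrics=("MaxL_nM",))
        alln = out[out.stratum == "all"].set_index("group")["n"]
        assert alln["yes"] == 81 and alln["no"] == 283
        by_sex = out[out.stratum != "all"].groupby("group")["n"].sum()
        assert by_sex["yes"] == 81 and by_sex["no"] == 283

    def test_empty_group(self):
        table = make_table(2)
        fake = pd.DataFrame(
            {
                "subject_id": ["X000", "X001"], "pathway": "with_pc",
                "MaxL_nM": [1.0, 2.0], "TMaxL_s": 1.0, "MaxR_nM_per_s": 1.0,
                "TMaxR_s": 1.0, "AUC_uM_s": 1.0, "CT_s": 1.0, "is_control": False,
            }
        )
        out = summarize_groups(fake, table, "pc_mutation", metrics=("MaxL_nM",))
        assert set(out.group) == {"no"}  # only observed groups are summarized


class TestEnvelopes:
    def test_identical_traces_zero_sd(self):
        t = np.arange(5.0)
        tr = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        env = envelope_curves({"g": [tr, tr.copy()]}, t)
        np.testing.assert_allclose(env["g_sd_nM"], 0.0)
        np.testing.assert_allclose(env["g_mean_nM"], tr)

    def test_mirror_traces_constant_mean(self):
        t = np.arange(4.0)
        f = np.array([1.0, 5.0, 2.0, 7.0])
        env = envelope_curves({"g": [f, -f + 6.0]}, t)
        np.testing.assert_allclose(env["g_mean_nM"], 3.0)

    def test_mean_within_min_max(self):
        rng = np.random.default_rng(3)
        t = np.arange(50.0)
        traces = [rng.uniform(0, 100, size=50) for _ in range(100)]
        env = envelope_curves({"g": traces}, t)
        arr = np.vstack(traces)
        assert (env["g_mean_nM"] >= arr.min(axis=0)).all()
        assert (env["g_mean_nM"] <= arr.max(axis=0)).all()

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            envelope_curves({"g": [np.zeros(3)]}, np.arange(4.0))
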