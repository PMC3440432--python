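"""Kinetics engine: initial state, mass-action RHS, stiff integration."""

import dataclasses

import numpy as np
import pytest

from thrombogen.kinetics import (
    PHYSIOLOGIC_MEAN,
    CompositionRangeWarning,
    CompositionWarning,
    PlasmaComposition,
    SimulationConfig,
    ThrombinWeights,
    initial_state,
    mass_action_rhs,
    simulate,
    total_thrombin_trace,
)
from thrombogen.metrics import compute_metrics
from thrombogen.model import load_model

from conftest import random_composition

r = dataclasses.replace


class TestComposition:
    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="fV_nM"):
            r(PHYSIOLOGIC_MEAN, fV_nM=-1.0)

    def test_outside_normal_range_warns(self):
        comp = r(PHYSIOLOGIC_MEAN, PC_nM=30.0)  # below accepted 50, inside observed 16-207
        with pytest.warns(CompositionWarning):
            comp.validate_ranges()

    def test_outside_observed_range_warns_strongly(self):
        comp = r(PHYSIOLOGIC_MEAN, fV_nM=80.0)  # above observed 60
        with pytest.warns(CompositionRangeWarning):
            comp.validate_ranges()

    def test_unknown_exclusion_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown exclusion flags"):
            r(PHYSIOLOGIC_MEAN, exclusions=frozenset({"on_heparin"}))


class TestInitialState:
    def test_physiologic_mean_entries(self, model):
        y0 = initial_state(model, PHYSIOLOGIC_MEAN, SimulationConfig())
        idx = model.species_index()
        assert y0[idx["II"]] == pytest.approx(1400.0)
        assert y0[idx["AT"]] == pytest.approx(3600.0)
        assert y0[idx["TF"]] == pytest.approx(0.005)
        assert y0[idx["Tm"]] == pytest.approx(1.0)
        assert y0[idx["VIIa"]] == pytest.approx(0.1)
        assert y0[idx["VII"]] == pytest.approx(9.9)
        assert y0[idx["PC"]] == pytest.approx(65.0)
        # everything else zero
        named = {"II", "AT", "TF", "Tm", "VIIa", "VII", "PC", "V", "VIII", "IX", "X", "TFPI"}
        for sym, i in idx.items():
            if sym not in named:
                assert y0[i] == 0.0, sym

    def test_zero_trigger(self, model):
        y0 = initial_state(model, PHYSIOLOGIC_MEAN, SimulationConfig(tf_trigger_pM=0.0))
        assert y0[model.species_index()["TF"]] == 0.0

    def test_base_submodel_state_has_no_pc_species(self, base_model):
        y0 = initial_state(base_model, PHYSIOLOGIC_MEAN, SimulationConfig(include_pc=False))
        assert len(y0) == len(base_model.species)
        assert set(base_model.species_symbols).isdisjoint({"Tm", "PC", "APC"})


class TestMassActionRHS:
    def test_toy_bimolecular(self, tmp_path):
        (tmp_path / "reactions.tsv").write_text(
            "reaction_id\tlhs\tarrow\trhs\tk_fwd_id\tk_rev_id\tsubmodel\n"
            "R1\tA + B\t->\tA=B\tk\t\tbase_extrinsic\n"
        )
        (tmp_path / "rates.tsv").write_text(
            "k_id\tvalue\tunits\tsource_note\nk\t0.01\tper_nanomolar_per_second\t-\n"
        )
        (tmp_path / "species.tsv").write_text(
            "symbol\tdisplay_name\tmoieties\tsubmodel\n"
            "A\ta\tTF:1\tbase_extrinsic\nB\tb\tVII:1\tbase_extrinsic\n"
            "A=B\tab\tTF:1;VII:1\tbase_extrinsic\n"
        )
        toy = load_model(tmp_path / "reactions.tsv", tmp_path / "rates.tsv")
        dy = mass_action_rhs(toy, np.array([10.0, 10.0, 0.0]))
        np.testing.assert_allclose(dy, [-1.0, -1.0, 1.0])

    def test_zero_state(self, model):
        np.testing.assert_array_equal(mass_action_rhs(model, np.zeros(len(model.species))), 0.0)

    def test_matches_per_reaction_loop(self, model):
        # brute-force oracle: loop over reactions, accumulate fluxes
        rng = np.random.default_rng(42)
        idx = model.species_index()
        for _ in range(25):
            y = rng.uniform(0.0, 100.0, size=len(model.species))
            expected = np.zeros_like(y)
            for rxn in model.reactions:
                v = model.rate_constants[rxn.rate_constant_id].value
                for sym, coef in rxn.reactants:
                    v *= y[idx[sym]] ** coef
                for sym, coef in rxn.reactants:
                    expected[idx[sym]] -= coef * v
                for sym, coef in rxn.products:
                    expected[idx[sym]] += coef * v
            got = mass_action_rhs(model, y)
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_nan_rejected(self, model):
        y = np.zeros(len(model.species))
        y[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            mass_action_rhs(model, y)


class TestSimulate:
    def test_grid_has_1201_points(self, control_timecourse):
        tc = control_timecourse
        assert len(tc.time) == 1201
        assert tc.time[0] == 0.0 and tc.time[-1] == 1200.0
        np.testing.assert_allclose(np.diff(tc.time), 1.0)

    def test_zero_trigger_no_thrombin(self, model):
        tc = simulate(model, PHYSIOLOGIC_MEAN, SimulationConfig(tf_trigger_pM=0.0))
        assert np.all(tc.thrombin <= 1e-6)

    def test_second_order_decay_closed_form(self, tmp_path):
        # single reaction II + AT -> II=AT with equal initial concentrations:
        # [II](t) = C0 / (1 + k*C0*t)
        import warnings

        (tmp_path / "reactions.tsv").write_text(
            "reaction_id\tlhs\tarrow\trhs\tk_fwd_id\tk_rev_id\tsubmodel\n"
            "R1\tII + AT\t->\tII=AT\tk41\t\tbase_extrinsic\n"
        )
        (tmp_path / "rates.tsv").write_text(
            "k_id\tvalue\tunits\tsource_note\nk41\t7.1e-6\tper_nanomolar_per_second\t-\n"
        )
        (tmp_path / "species.tsv").write_text(
            "symbol\tdisplay_name\tmoieties\tsubmodel\n"
            "II\tprothrombin\tII:1\tbase_extrinsic\n"
            "AT\tantithrombin\tAT:1\tbase_extrinsic\n"
            "II=AT\tcomplex\tII:1;AT:1\tbase_extrinsic\n"
        )
        toy = load_model(tmp_path / "reactions.tsv", tmp_path / "rates.tsv")
        k, c0 = 7.1e-6, 100.0
        comp = r(PHYSIOLOGIC_MEAN, subject_id="decay", fII_uM=0.1, AT_uM=0.1)
        cfg = SimulationConfig(tf_trigger_pM=0.0, tm_nM=0.0, fviia_fraction=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # thrombin species absent from the toy
            tc = simulate(toy, comp, cfg)
        expected = c0 / (1.0 + k * c0 * tc.time)
        np.testing.assert_allclose(tc.trace("II"), expected, rtol=1e-6)

    def test_conservation_within_tolerance(self, control_timecourse):
        assert control_timecourse.diagnostics["max_conservation_drift"] < 1e-3

    def test_deterministic(self, model):
        a = simulate(model, PHYSIOLOGIC_MEAN)
        b = simulate(model, PHYSIOLOGIC_MEAN)
        np.testing.assert_array_equal(a.thrombin, b.thrombin)

    def test_concentrations_nonnegative(self, control_timecourse):
        assert control_timecourse.concentrations.min() >= 0.0

    def test_submodel_equivalence_tm_zero(self, model, base_model):
        rng = np.random.default_rng(7)
        comp = r(random_composition(rng), PC_nM=0.0)
        cfg = SimulationConfig(tm_nM=0.0)
        full = simulate(model, comp, cfg)
        base = simulate(base_model, comp, r(cfg, include_pc=False))
        tol = 10 * (cfg.rtol * full.thrombin.max() + cfg.atol)
        assert np.abs(full.thrombin - base.thrombin).max() < tol


@pytest.fixture(scope="module")
def metric_of(model):
    cache = {}

    def compute(**kw):
        key = tuple(sorted(kw.items()))
        if key not in cache:
            comp = r(PHYSIOLOGIC_MEAN, subject_id=str(key), **kw)
            tc = simulate(model, comp)
            cache[key] = compute_metrics(tc.time, tc.thrombin)
        return cache[key]

    return compute


class TestDirectionalEffects:
    def test_pc_raise_decreases_maxl_and_auc(self, metric_of):
        lo, hi = metric_of(PC_nM=47.0), metric_of(PC_nM=110.0)
        assert lo.max_level_nM > hi.max_level_nM
        assert lo.auc_uM_s > hi.auc_uM_s

    def test_fii_raise_increases_auc(self, metric_of):
        assert metric_of(fII_uM=1.8).auc_uM_s > metric_of().auc_uM_s

    def test_tfpi_raise_increases_ct(self, metric_of):
        assert metric_of(TFPI_nM=3.5).clot_time_s > metric_of().clot_time_s

    def test_at_raise_increases_ct(self, metric_of):
        assert metric_of(AT_uM=4.5).clot_time_s > metric_of().clot_time_s

    def test_exhaustion_limit(self, model):
        # no inhibitors: the full prothrombin pool ends up as active thrombin
        comp = r(PHYSIOLOGIC_MEAN, subject_id="exhaust", AT_uM=0.0, TFPI_nM=0.0, PC_nM=0.0)
        cfg = SimulationConfig(tm_nM=0.0, duration_s=3600.0)
        tc = simulate(model, comp, cfg)
        plateau = tc.trace("IIa")[-1] + tc.trace("mIIa")[-1]
        assert plateau == pytest.approx(1400.0, rel=0.05)


class TestToleranceRobustness:
    def test_halved_tolerances_stable(self, model, control_timecourse):
        m1 = compute_metrics(control_timecourse.time, control_timecourse.thrombin)
        cfg = SimulationConfig(rtol=0.5e-8, atol=0.5e-12)
        tc = simulate(model, PHYSIOLOGIC_MEAN, cfg)
        m2 = compute_metrics(tc.time, tc.thrombin)
        assert m2.max_level_nM == pytest.approx(m1.max_level_nM, rel=1e-3)
        assert m2.auc_uM_s == pytest.approx(m1.auc_uM_s, rel=1e-3)


class TestTotalThrombin:
    def test_weighted_sum(self, control_timecourse):
        tc = control_timecourse
        expected = tc.trace("IIa") + 1.2 * tc.trace("mIIa")
        np.testing.assert_allclose(tc.thrombin, expected)

    def test_weight_zero_miia(self, control_timecourse):
        trace = total_thrombin_trace(control_timecourse, ThrombinWeights(w_miia=0.0))
        np.testing.assert_array_equal(trace, control_timecourse.trace("IIa"))

    def test_missing_species_warns(self, base_model):
        cfg = SimulationConfig(include_pc=False)
        tc = simulate(base_model, PHYSIOLOGIC_MEAN, cfg)
        with pytest.warns(UserWarning, match="absent from submodel"):
            total_thrombin_trace(tc, ThrombinWeights(include_tm_bound=True))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ThrombinWeights(w_iia=-1.0)
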