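"""Differential testing, discretization and series assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbnpipe import (
    DataError,
    GroundTruthSpec,
    NoiseModel,
    PreprocessConfig,
    assemble_series,
    emulate_expression,
    estimate_tech_correlation,
    fit_differential_calls,
    make_ground_truth_model,
    precision_weights,
    sample_time_series,
    summarize_antibodies,
)
from dbnpipe.synthetic_data import EXPRESSION_COLUMNS


def _table(rows):
    return pd.DataFrame(rows, columns=list(EXPRESSION_COLUMNS))


def _null_protein_table(rng, n_molecules=4, n_times=6, sd=0.2, rho=0.0, mean_fn=None):
    rows = []
    for i in range(n_molecules):
        mol = f"M{i}"
        base = 8.0 + i if mean_fn is None else mean_fn(i)
        for cond in ("control", "EGF"):
            for t in range(n_times):
                for b in range(1, 4):
                    shared = rng.normal(0, sd * np.sqrt(rho))
                    for k in range(1, 4):
                        v = base + shared + rng.normal(0, sd * np.sqrt(1 - rho))
                        rows.append((mol, mol, "cyt_protein", cond, t, b, k, v, np.nan))
    return _table(rows)


class TestTechnicalCorrelation:
    def test_duplicated_technical_replicates_give_correlation_one(self):
        rng = np.random.default_rng(0)
        tbl = _null_protein_table(rng, n_molecules=1)
        # make tech reps exact copies of tech rep 1
        first = tbl[tbl.tech_rep == 1].set_index(["condition", "time", "bio_rep"])["value"]
        tbl["value"] = [
            first.loc[(r.condition, r.time, r.bio_rep)] for r in tbl.itertuples()
        ]
        rho = estimate_tech_correlation(tbl)
        assert rho.iloc[0] >= 0.99

    def test_independent_noise_gives_near_zero_correlation(self):
        rng = np.random.default_rng(1)
        tbl = _null_protein_table(rng, n_molecules=3, n_times=150, rho=0.0)
        rho = estimate_tech_correlation(tbl)
        assert (rho.abs() < 0.05).all()

    def test_recovers_generating_correlation(self):
        spec = GroundTruthSpec(node_names=("A",), edges=(), stim_map={})
        model = make_ground_truth_model(spec)
        s = sample_time_series(model, "control", "cyt_protein", T=1000, seed=0, initial_states={"A": 0})
        s.states.loc["A"] = 0
        tbl = emulate_expression([s], NoiseModel(tech_rho=0.8), seed=2)
        rho = estimate_tech_correlation(tbl)
        assert 0.75 < rho.iloc[0] < 0.85

    def test_single_technical_replicate_returns_zero(self):
        rng = np.random.default_rng(3)
        tbl = _null_protein_table(rng, n_molecules=1)
        tbl = tbl[tbl.tech_rep == 1]
        assert estimate_tech_correlation(tbl).iloc[0] == 0.0


class TestPrecisionWeights:
    def test_homoscedastic_data_give_constant_weights(self):
        rng = np.random.default_rng(4)
        tbl = _null_protein_table(rng, n_molecules=6, n_times=10)
        w = precision_weights(tbl)
        assert (w > 0).all()
        assert w.max() / w.min() < 1.25

    def test_variance_doubling_at_low_means_halves_weights(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(40):
            mol = f"M{i}"
            low = i < 20
            base = 6.0 if low else 10.0
            sd = 0.2 * np.sqrt(2) if low else 0.2
            for t in range(3):
                for b in range(1, 4):
                    for k in range(1, 4):
                        rows.append((mol, mol, "cyt_protein", "control", t, b, k, base + rng.normal(0, sd), np.nan))
        tbl = _table(rows)
        w = precision_weights(tbl)
        ratio = w[tbl["value"].to_numpy() < 8].mean() / w[tbl["value"].to_numpy() >= 8].mean()
        assert 0.4 < ratio < 0.6

    def test_few_groups_fall_back_to_constant(self):
        rng = np.random.default_rng(6)
        tbl = _null_protein_table(rng, n_molecules=1, n_times=2)
        np.testing.assert_array_equal(precision_weights(tbl), 1.0)


class TestDifferentialCalls:
    def test_copied_control_values_give_zero_logfc_and_call(self):
        rng = np.random.default_rng(7)
        tbl = _null_protein_table(rng, n_molecules=2, n_times=5)
        ctrl = tbl[tbl.condition == "control"].set_index(["molecule", "time", "bio_rep", "tech_rep"])["value"]
        stim = tbl.condition == "EGF"
        tbl.loc[stim, "value"] = [
            ctrl.loc[(r.molecule, r.time, r.bio_rep, r.tech_rep)]
            for r in tbl[stim].itertuples()
        ]
        calls = fit_differential_calls(tbl)
        np.testing.assert_allclose(calls["log_fc"], 0.0, atol=1e-10)
        assert (calls["call"] == 0).all()

    def test_ten_sigma_shift_called_up(self):
        rng = np.random.default_rng(8)
        tbl = _null_protein_table(rng, n_molecules=4, n_times=6, sd=0.2)
        bump = (tbl.condition == "EGF") & (tbl.molecule == "M0") & (tbl.time == 2)
        tbl.loc[bump, "value"] += 2.0  # 10 sigma
        calls = fit_differential_calls(tbl)
        hit = calls[(calls.molecule == "M0") & (calls.time == 2)]
        assert (hit["call"] == 1).all()
        others = calls[~((calls.molecule == "M0") & (calls.time == 2))]
        assert (others["call"] == 0).mean() > 0.95

    def test_missing_control_is_an_error(self):
        rng = np.random.default_rng(9)
        tbl = _null_protein_table(rng, n_molecules=1)
        with pytest.raises(DataError, match="control"):
            fit_differential_calls(tbl[tbl.condition != "control"])

    def test_single_replicate_has_zero_residual_df(self):
        rng = np.random.default_rng(10)
        tbl = _null_protein_table(rng, n_molecules=1, n_times=4)
        tbl = tbl[(tbl.bio_rep == 1) & (tbl.tech_rep == 1)]
        with pytest.raises(DataError, match="degrees of freedom"):
            fit_differential_calls(tbl)

    def test_calls_invariant_under_global_shift(self):
        rng = np.random.default_rng(11)
        tbl = _null_protein_table(rng, n_molecules=3, n_times=6)
        tbl.loc[(tbl.condition == "EGF") & (tbl.time == 1), "value"] += 1.5
        shifted = tbl.copy()
        shifted["value"] += 5.0
        a = fit_differential_calls(tbl)
        b = fit_differential_calls(shifted)
        np.testing.assert_allclose(a["log_fc"], b["log_fc"], atol=1e-8)
        np.testing.assert_array_equal(a["call"], b["call"])

    def test_fdr_monotonicity_never_creates_calls_when_tightened(self):
        rng = np.random.default_rng(12)
        tbl = _null_protein_table(rng, n_molecules=3, n_times=6)
        tbl.loc[(tbl.condition == "EGF") & (tbl.time == 0), "value"] += 0.4
        loose = fit_differential_calls(tbl, PreprocessConfig(fdr_threshold=0.05))
        tight = fit_differential_calls(tbl, PreprocessConfig(fdr_threshold=0.005))
        was_zero = loose["call"] == 0
        assert (tight["call"][was_zero] == 0).all()

    def test_call_accuracy_nondecreasing_in_effect_size(self, study_series):
        from dbnpipe import discretize_table

        accs = []
        for effect in (0.3, 0.8, 1.6):
            tbl = emulate_expression(study_series, NoiseModel(effect_size=effect), seed=13)
            _, _, rec = discretize_table(tbl)
            truth = [s for s in study_series if s.condition != "control"]
            correct = total = 0
            for t in truth:
                r = next(s for s in rec if (s.context, s.condition) == (t.context, t.condition))
                correct += (r.states.loc[list(t.molecules)].to_numpy() == t.states.to_numpy()).sum()
                total += t.states.size
            accs.append(correct / total)
        assert accs[0] <= accs[1] <= accs[2]


class TestSummaryAndAssembly:
    @pytest.mark.parametrize(
        "calls,expected",
        [([1, 1, 0], 1), ([1, -1], 0), ([-1], -1), ([-1, -1, 1], -1), ([0, 0], 0)],
    )
    def test_sign_of_mean_rule(self, calls, expected):
        df = pd.DataFrame(
            {
                "molecule": "M0",
                "context": "cyt_protein",
                "condition": "EGF",
                "time": 0,
                "antibody": [f"ab{i}" for i in range(len(calls))],
                "call": calls,
            }
        )
        out = summarize_antibodies(df)
        assert out["call"].iloc[0] == expected

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=6))
    def test_summary_is_sign_of_mean_for_any_call_set(self, calls):
        df = pd.DataFrame(
            {
                "molecule": "M0",
                "context": "transcript",
                "condition": "GLI",
                "time": 3,
                "antibody": [f"ab{i}" for i in range(len(calls))],
                "call": calls,
            }
        )
        assert summarize_antibodies(df)["call"].iloc[0] == int(np.sign(np.mean(calls)))

    def test_study_shaped_input_yields_nine_series_of_fourteen_points(self, study_discretized):
        _, _, series = study_discretized
        assert len(series) == 9
        assert all(s.n_time == 14 for s in series)
        assert all(len(s.molecules) == 13 for s in series)

    def test_single_condition_single_context_gives_one_series(self):
        summary = pd.DataFrame(
            [("A", "cyt_protein", "EGF", t, 1) for t in range(3)]
            + [("B", "cyt_protein", "EGF", t, 0) for t in range(3)],
            columns=["molecule", "context", "condition", "time", "call"],
        )
        series = assemble_series(summary)
        assert len(series) == 1
        assert series[0].stim == {"EGF_stim": 1, "SHH_stim": 0, "GLI_stim": 0}

    def test_gli_condition_sets_only_gli_stim(self):
        summary = pd.DataFrame(
            [("A", "transcript", "GLI", t, 0) for t in range(2)],
            columns=["molecule", "context", "condition", "time", "call"],
        )
        (series,) = assemble_series(summary)
        assert series.stim == {"EGF_stim": 0, "SHH_stim": 0, "GLI_stim": 1}

    def test_missing_time_point_reported(self):
        summary = pd.DataFrame(
            [("A", "cyt_protein", "EGF", t, 0) for t in (0, 1, 3)],
            columns=["molecule", "context", "condition", "time", "call"],
        )
        with pytest.raises(DataError, match=r"\[2\]"):
            assemble_series(summary)
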