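"""Ground-truth construction and expression emulation."""

import numpy as np
import pandas as pd
import pytest

from dbnpipe import (
    ConfigurationError,
    DataError,
    GroundTruthSpec,
    NoiseModel,
    emulate_expression,
    forward_sample,
    make_ground_truth_model,
    sample_study_series,
    sample_time_series,
    study_ground_truth,
)
from dbnpipe.dbn_core import CONTROL_CONDITION


class TestGroundTruthConstruction:
    def test_edgeless_spec_gives_uniform_unstimulated_rows(self):
        model = make_ground_truth_model(GroundTruthSpec(edges=()))
        for m in model.structure.molecules:
            cpt = model.cpts[m]
            # stimulation off <=> fixed index even blocks; context-only nodes
            # have a single stim-free row per context
            f0 = model.structure.fixed_cfg_index(m, "cyt_protein", {s: 0 for s in ("EGF_stim", "SHH_stim", "GLI_stim")})
            np.testing.assert_allclose(cpt.trans[f0], 1 / 3, atol=1e-9)

    def test_stimulation_biases_target_upward(self):
        model = make_ground_truth_model(GroundTruthSpec(edges=()))
        st = model.structure
        on = st.fixed_cfg_index("EGFR", "cyt_protein", {"EGF_stim": 1, "SHH_stim": 0, "GLI_stim": 0})
        assert model.cpts["EGFR"].trans[on, 0, 2] == pytest.approx(0.9)

    def test_deterministic_copy_edge(self):
        spec = GroundTruthSpec(node_names=("A", "B"), edges=(("A", "B"),), edge_strength=1.0, stim_map={})
        model = make_ground_truth_model(spec)
        for s in (-1, 0, 1):
            pa = s + 1
            assert model.cpts["B"].trans[0, pa, s + 1] == pytest.approx(1.0, abs=1e-9)

    def test_partial_strength_splits_remaining_mass(self):
        spec = GroundTruthSpec(node_names=("A", "B"), edges=(("A", "B"),), edge_strength=0.7, stim_map={})
        model = make_ground_truth_model(spec)
        for s in (-1, 0, 1):
            row = model.cpts["B"].trans[0, s + 1]
            assert row[s + 1] == pytest.approx(0.7)
            off = np.delete(row, s + 1)
            np.testing.assert_allclose(off, 0.15)
            assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_inhibitory_edge_flips_target_sign(self):
        spec = GroundTruthSpec(node_names=("A", "B"), edges=(("A", "B", -1),), edge_strength=0.8, stim_map={})
        model = make_ground_truth_model(spec)
        assert model.cpts["B"].trans[0, 2, 0] == pytest.approx(0.8)  # A=+1 -> B=-1

    def test_unknown_edge_node_rejected(self):
        with pytest.raises(ConfigurationError):
            GroundTruthSpec(node_names=("A",), edges=(("A", "Z"),))


class TestSampling:
    def test_deterministic_chain_copies_clamped_state(self):
        spec = GroundTruthSpec(node_names=("A", "B"), edges=(("A", "B"),), edge_strength=1.0, stim_map={})
        model = make_ground_truth_model(spec)
        s = sample_time_series(model, "control", "cyt_protein", T=6, seed=0, initial_states={"A": 1, "B": 1})
        # A has no parent and relaxes to uniform, but B always copies A(t-1)
        a = s.states.loc["A"].to_numpy()
        b = s.states.loc["B"].to_numpy()
        np.testing.assert_array_equal(b[1:], a[:-1])

    def test_empirical_marginals_of_edgeless_model_are_uniform(self):
        spec = GroundTruthSpec(node_names=("A", "B", "C"), edges=(), stim_map={})
        model = make_ground_truth_model(spec)
        rng = np.random.default_rng(7)
        draws = np.concatenate(
            [
                forward_sample(model, "control", "cyt_protein", T=14, seed=rng).states.to_numpy().ravel()
                for _ in range(2000)
            ]
        )
        freqs = np.bincount(draws + 1, minlength=3) / draws.size
        # 84k draws: a 5-sigma binomial band around 1/3 is ~ +/- 0.008
        assert np.all(np.abs(freqs - 1 / 3) < 0.008)

    def test_two_node_joint_matches_product_of_cpt_entries(self):
        """Forward-sampled (parent(t-1), child(t)) frequencies converge to
        P(parent) * P(child | parent), total variation < 0.01."""
        spec = GroundTruthSpec(node_names=("A", "B"), edges=(("A", "B"),), edge_strength=0.6, stim_map={})
        model = make_ground_truth_model(spec)
        rng = np.random.default_rng(8)
        prev, curr = [], []
        for _ in range(600):
            arr = forward_sample(model, "control", "cyt_protein", T=180, seed=rng).states.to_numpy()
            prev.append(arr[0, :-1])
            curr.append(arr[1, 1:])
        prev, curr = np.concatenate(prev), np.concatenate(curr)
        joint = np.zeros((3, 3))
        for a, b in zip(prev, curr):
            joint[a + 1, b + 1] += 1
        joint /= joint.sum()
        f0 = model.structure.fixed_cfg_index("B", "cyt_protein", {"EGF_stim": 0, "SHH_stim": 0, "GLI_stim": 0})
        expected = (1 / 3) * model.cpts["B"].trans[f0]  # A is uniform marginally
        assert 0.5 * np.abs(joint - expected).sum() < 0.01

    def test_identical_seeds_give_identical_study_series(self, study_model):
        a = sample_study_series(study_model, seed=3)
        b = sample_study_series(study_model, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.states, y.states)

    def test_study_design_shape(self, study_series):
        stimulated = [s for s in study_series if s.condition != CONTROL_CONDITION]
        assert len(stimulated) == 9
        assert all(s.n_time == 14 for s in stimulated)
        assert {s.context for s in stimulated} == {"cyt_protein", "nuc_protein", "transcript"}


class TestExpressionEmulation:
    def test_missing_control_rejected(self, study_model):
        stim_only = [s for s in sample_study_series(study_model, seed=1, include_controls=True) if s.condition != CONTROL_CONDITION]
        with pytest.raises(DataError, match="control"):
            emulate_expression(stim_only, NoiseModel(), seed=0)

    def test_null_states_make_stimulated_match_control_in_law(self):
        spec = GroundTruthSpec(node_names=("A",), edges=(), stim_map={})
        model = make_ground_truth_model(spec)
        zero = {"A": 0}
        series = []
        for cond in (CONTROL_CONDITION, "EGF"):
            s = sample_time_series(model, cond, "cyt_protein", T=60, seed=0, initial_states=zero)
            s.states.loc["A"] = 0
            series.append(s)
        tbl = emulate_expression(series, NoiseModel(tech_rho=0.3), seed=5)
        ctrl = tbl[tbl.condition == CONTROL_CONDITION]["value"]
        stim = tbl[tbl.condition == "EGF"]["value"]
        # 540 values of sd 0.2 per arm: a 3-sigma band on the mean difference
        assert abs(ctrl.mean() - stim.mean()) < 0.04
        assert abs(ctrl.std() - stim.std()) < 0.04

    def test_technical_replicates_correlate_at_tech_rho(self):
        spec = GroundTruthSpec(node_names=("A",), edges=(), stim_map={})
        model = make_ground_truth_model(spec)
        s = sample_time_series(model, CONTROL_CONDITION, "cyt_protein", T=1200, seed=0, initial_states={"A": 0})
        s.states.loc["A"] = 0
        tbl = emulate_expression([s], NoiseModel(tech_rho=0.9, n_tech=2), seed=6)
        wide = tbl.pivot_table(index=["time", "bio_rep"], columns="tech_rep", values="value")
        r = np.corrcoef(wide[1], wide[2])[0, 1]
        assert 0.88 < r < 0.92

    def test_same_seed_gives_identical_tables(self, study_series):
        t1 = emulate_expression(study_series, NoiseModel(), seed=9)
        t2 = emulate_expression(study_series, NoiseModel(), seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_transcript_rows_carry_detection_p(self, study_expression):
        tr = study_expression[study_expression.context == "transcript"]
        pr = study_expression[study_expression.context != "transcript"]
        assert tr["detection_p"].notna().all()
        assert pr["detection_p"].isna().all()
        assert (tr["tech_rep"] == 1).all()


def test_round_trip_recovers_states_with_large_effects():
    """With effects >= 6 sigma and 0-dominated dynamics, discretization
    recovers at least 95% of the planted trinary states."""
    from dbnpipe import discretize_table

    mols = study_ground_truth().node_names
    spec = GroundTruthSpec(edges=tuple((m, m) for m in mols), edge_strength=0.95)
    model = make_ground_truth_model(spec)
    zero = {m: 0 for m in mols}
    series = sample_study_series(model, seed=21, include_controls=True, initial_states=zero)
    noise = NoiseModel(sigma0=0.2, effect_size=1.2)  # 6 sigma effects
    table = emulate_expression(series, noise, seed=22)
    _, _, recovered = discretize_table(table)
    truth = [s for s in series if s.condition != CONTROL_CONDITION]
    correct = total = 0
    for t in truth:
        r = next(s for s in recovered if (s.context, s.condition) == (t.context, t.condition))
        correct += (r.states.loc[list(t.molecules)].to_numpy() == t.states.to_numpy()).sum()
        total += t.states.size
    assert correct / total >= 0.95
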