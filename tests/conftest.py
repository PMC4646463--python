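"""Shared fixtures: small hand-built models and study-shaped synthetic data."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from dbnpipe import (
    CPTSet,
    DBNModel,
    DBNStructure,
    NodeCPT,
    NoiseModel,
    TrinarySeries,
    emulate_expression,
    make_ground_truth_model,
    sample_study_series,
    study_ground_truth,
)

logging.disable(logging.WARNING)


def make_bare_model(molecules, parent_sets, trans_rows=None, strength=0.8):
    """A context/stimulation-free DBN for small exact-oracle tests.

    ``trans_rows`` may give explicit (3**k, 3) transition arrays per node;
    otherwise every node copies the signed sum of its parents with the given
    strength (uniform when parentless).  Initial distributions are uniform.
    """
    structure = DBNStructure.bare(molecules, parent_sets)
    cpts = CPTSet()
    for m in structure.molecules:
        parents = structure.parent_sets[m]
        npa = 3 ** len(parents)
        if trans_rows is not None and m in trans_rows:
            trans = np.asarray(trans_rows[m], dtype=float)[None, :, :]
        else:
            trans = np.empty((1, npa, 3))
            for pa in range(npa):
                states, rem = [], pa
                for _ in parents:
                    states.append(rem % 3 - 1)
                    rem //= 3
                if not parents:
                    trans[0, pa] = 1.0 / 3.0
                else:
                    target = int(np.sign(sum(states)))
                    row = np.full(3, (1.0 - strength) / 2.0)
                    row[target + 1] = strength
                    trans[0, pa] = row
        trans = np.clip(trans, 1e-12, None)
        trans /= trans.sum(axis=-1, keepdims=True)
        init = np.full((1, 3), 1.0 / 3.0)
        cpts[m] = NodeCPT((), parents, trans, init)
    return DBNModel(structure, cpts)


def bare_series(molecules, array, condition="control"):
    return TrinarySeries(pd.DataFrame(np.asarray(array), index=list(molecules)), condition=condition)


@pytest.fixture(scope="session")
def study_model():
    return make_ground_truth_model(study_ground_truth(0.9))


@pytest.fixture(scope="session")
def study_series(study_model):
    """Nine stimulated study-shaped series plus per-context controls."""
    return sample_study_series(study_model, seed=11, include_controls=True)


@pytest.fixture(scope="session")
def study_expression(study_series):
    """Replicate-level expression table for the study-shaped series."""
    return emulate_expression(study_series, NoiseModel(effect_size=1.2), seed=12)


@pytest.fixture(scope="session")
def study_discretized(study_expression):
    from dbnpipe import discretize_table

    return discretize_table(study_expression)
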