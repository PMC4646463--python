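"""Posterior prediction of unobserved molecules by likelihood weighting.

Sequential importance sampling with per-step resampling: N particles are
initialized from the learned t=0 distributions, weighted by the likelihood
of the observed nodes, and at every subsequent time point whole particles
are resampled proportional to their weights before unobserved nodes are
drawn from their conditional probability tables and observed nodes
contribute fresh likelihood factors.  The reported posterior at time t,

    P(U(t) = v | o(0), ..., o(t)) ~= sum_s w_s(t) 1{u_s(t)=v} / sum_s w_s(t),

is the filtered state distribution of each target molecule.  Because the
learned CPTs are pseudo-count smoothed, every observation has positive
probability; a zero total weight therefore signals a modeling bug and is
raised, never silently renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dbn_core import (
    CONTROL_CONDITION,
    STATES,
    ConfigurationError,
    DataError,
    DBNModel,
    N_STATES,
    TrinarySeries,
    _parent_config_index,
    stim_from_condition,
)

__all__ = ["EvidenceSeries", "PosteriorTable", "DegeneracyError", "predict_posterior", "map_state"]


class DegeneracyError(RuntimeError):
    """All particle weights vanished: the evidence is impossible under the model."""

    def __init__(self, t: int):
        super().__init__(f"all likelihood weights are zero at time {t}")
        self.t = t


@dataclass
class EvidenceSeries:
    """Partially observed series: NaN entries mark hidden (target) states.

    Stimulation and context are always observed; hidden cells are predicted.
    """

    observed: pd.DataFrame  # molecules x time, float with NaN for hidden
    condition: str = CONTROL_CONDITION
    context: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        vals = self.observed.to_numpy(dtype=float)
        seen = vals[~np.isnan(vals)]
        if seen.size and not np.isin(seen, STATES).all():
            raise DataError("observed states must lie in {-1, 0, 1}")

    @property
    def targets(self) -> tuple[str, ...]:
        mask = self.observed.isna().any(axis=1)
        return tuple(self.observed.index[mask])

    @property
    def stim(self) -> dict[str, int]:
        return stim_from_condition(self.condition)

    @classmethod
    def from_series(cls, series: TrinarySeries, hide: Sequence[str]) -> "EvidenceSeries":
        missing = set(hide) - set(series.molecules)
        if missing:
            raise ConfigurationError(f"hidden targets absent from the node set: {sorted(missing)}")
        obs = series.states.astype(float).copy()
        obs.loc[list(hide)] = np.nan
        return cls(obs, condition=series.condition, context=series.context, name=series.name)


@dataclass
class PosteriorTable:
    """Per target molecule and time point: probability vector over (-1, 0, 1)."""

    probs: dict[str, np.ndarray]  # node -> (T, 3)
    step_mean_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for node, arr in self.probs.items():
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-9:
                raise DataError(f"posterior rows of {node!r} do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, arr in self.probs.items():
            for t in range(arr.shape[0]):
                rows.append((node, t, *arr[t]))
        return pd.DataFrame(rows, columns=["node", "time", "p_down", "p_none", "p_up"])


def _sample_categorical_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    idx = (u[:, None] > cum[:, :-1]).sum(axis=1)
    return idx  # 0..2


def predict_posterior(
    model: DBNModel,
    evidence: EvidenceSeries,
    N: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PosteriorTable:
    """Likelihood-weighting posterior over every hidden cell of the evidence."""
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    st = model.structure
    mols = st.molecules
    if tuple(evidence.observed.index) != mols:
        raise DataError("evidence molecule set does not match the model")
    obs = evidence.observed.to_numpy(dtype=float)  # (n_mol, T)
    T = obs.shape[1]
    cols = {m: i for i, m in enumerate(mols)}
    fixed = {m: st.fixed_cfg_index(m, evidence.context, evidence.stim) for m in mols}
    trans = {m: model.cpts[m].trans[fixed[m]] for m in mols}  # (3^k, 3)
    init = {m: model.cpts[m].init[fixed[m]] for m in mols}  # (3,)
    pa_cols = {m: [cols[p] for p in model.cpts[m].parents] for m in mols}
    targets = evidence.targets

    states = np.zeros((N, len(mols)), dtype=np.int8)
    w = np.ones(N)
    for m in mols:
        i = cols[m]
        if np.isnan(obs[i, 0]):
            states[:, i] = _sample_categorical_rows(np.tile(init[m], (N, 1)), rng) - 1
        else:
            s = int(obs[i, 0])
            states[:, i] = s
            w *= init[m][s + 1]

    post = {m: np.zeros((T, N_STATES)) for m in targets}
    mean_w = np.zeros(T)

    def record(t: int) -> None:
        tot = w.sum()
        if tot <= 0.0:
            raise DegeneracyError(t)
        mean_w[t] = tot / N
        for m in targets:
            i = cols[m]
            for s_idx in range(N_STATES):
                post[m][t, s_idx] = w[(states[:, i] + 1) == s_idx].sum() / tot

    record(0)
    for t in range(1, T):
        # resample whole particles; weights then carry only slice-t evidence
        idx = rng.choice(N, size=N, p=w / w.sum())
        prev = states[idx].copy()
        states = np.empty_like(prev)
        w = np.ones(N)
        for m in mols:
            i = cols[m]
            pa_idx = _parent_config_index(prev, pa_cols[m])
            probs = trans[m][pa_idx]  # (N, 3)
            if np.isnan(obs[i, t]):
                states[:, i] = _sample_categorical_rows(probs, rng) - 1
            else:
                s = int(obs[i, t])
                states[:, i] = s
                w *= probs[:, s + 1]
        record(t)
    return PosteriorTable(post, mean_w)


def map_state(
    posterior: PosteriorTable,
    prior_marginals: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Most probable state per target/time with conservative tie handling.

    Exact three-way ties and any tie involving the 0 state resolve to 0; a
    -1/+1 tie resolves to the state with the larger prior marginal (if
    provided), otherwise to 0.
    """
    out = {}
    for node, arr in posterior.probs.items():
        calls = np.zeros(arr.shape[0], dtype=np.int8)
        for t in range(arr.shape[0]):
            p = arr[t]
            m = p.max()
            tied = [s_idx for s_idx in range(N_STATES) if p[s_idx] == m]
            if len(tied) == 1:
                calls[t] = tied[0] - 1
            elif len(tied) == 3 or 1 in tied:
                calls[t] = 0
            else:  # two-way tie between -1 and +1
                if prior_marginals is not None and node in prior_marginals:
                    pm = np.asarray(prior_marginals[node], dtype=float)
                    if pm[0] != pm[2]:
                        calls[t] = -1 if pm[0] > pm[2] else 1
                    else:
                        calls[t] = 0
                else:
                    calls[t] = 0
        out[node] = calls
    df = pd.DataFrame(out).T
    df.index.name = "node"
    return df
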