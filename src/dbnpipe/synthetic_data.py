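"""Ground-truth DBN generators and replicate-level expression emulation.

The study design being emulated: 13 molecules measured in three contexts
(cytoplasmic protein, nuclear protein, transcript) over 14 time points under
sustained stimulation (EGF, SHH or EGF+SHH for protein; EGF, GLI or EGF+GLI
for transcript — GLI1 induction stands in for SHH stimulation on the
transcriptome), with 3 biological x 3 technical replicates for protein and
biological triplicates for transcripts.  The generator produces (a) trinary
ground-truth state series from a known transition model and (b) continuous
log-intensity tables with a mean-variance trend and within-biological-
replicate technical correlation, so every downstream stage (discretization,
structure search, inference, bootstrap) can be tested without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dbn_core import (
    CONTROL_CONDITION,
    DEFAULT_MOLECULES,
    DEFAULT_STIM_MAP,
    STIM_NODES,
    ConfigurationError,
    CPTSet,
    DataError,
    DBNModel,
    DBNStructure,
    N_STATES,
    NodeCPT,
    TrinarySeries,
    forward_sample,
)

__all__ = [
    "GroundTruthSpec",
    "NoiseModel",
    "make_ground_truth_model",
    "sample_time_series",
    "sample_study_series",
    "emulate_expression",
    "study_ground_truth",
    "literature_ground_truth",
    "STUDY_CONDITIONS",
    "EXPRESSION_COLUMNS",
]

#: Stimulations recorded per context in the study design: nine series total.
STUDY_CONDITIONS: dict[str, tuple[str, ...]] = {
    "cyt_protein": ("EGF", "SHH", "EGF+SHH"),
    "nuc_protein": ("EGF", "SHH", "EGF+SHH"),
    "transcript": ("EGF", "GLI", "EGF+GLI"),
}

EXPRESSION_COLUMNS = (
    "molecule",
    "antibody",
    "context",
    "condition",
    "time",
    "bio_rep",
    "tech_rep",
    "value",
    "detection_p",
)


@dataclass
class GroundTruthSpec:
    """A planted transition model: directed t-1 -> t edges with signs.

    ``edges`` entries are ``(parent, child)`` or ``(parent, child, sign)``
    with sign +1 (activation, default) or -1 (inhibition).  ``edge_strength``
    is the probability mass placed on the parent-determined child state,
    either one scalar or a per-edge mapping keyed by ``(parent, child)``.
    Stimulation nodes (via ``stim_map``) push their targets toward +1 with
    the default strength while switched on.
    """

    node_names: tuple[str, ...] = DEFAULT_MOLECULES
    edges: tuple = ()
    edge_strength: float | Mapping[tuple[str, str], float] = 0.9
    stim_map: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_STIM_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        self.node_names = tuple(self.node_names)
        known = set(self.node_names)
        norm = []
        for e in self.edges:
            if len(e) == 2:
                parent, child, sign = e[0], e[1], 1
            else:
                parent, child, sign = e
            if parent not in known or child not in known:
                raise ConfigurationError(f"edge {parent}->{child} references an unknown node")
            if sign not in (-1, 1):
                raise ConfigurationError("edge sign must be +1 or -1")
            norm.append((parent, child, sign))
        self.edges = tuple(norm)
        self.stim_map = {s: tuple(t) for s, t in self.stim_map.items()}
        for s, targets in self.stim_map.items():
            for t in targets:
                if t not in known:
                    raise ConfigurationError(f"stimulation target {t!r} is not a node")
        for strength in self._strengths().values():
            if not 0.0 <= strength <= 1.0:
                raise ConfigurationError("edge_strength must lie in [0, 1]")

    def _default_strength(self) -> float:
        if isinstance(self.edge_strength, Mapping):
            vals = list(self.edge_strength.values())
            return float(np.mean(vals)) if vals else 0.9
        return float(self.edge_strength)

    def _strengths(self) -> dict[tuple[str, str], float]:
        out = {}
        for parent, child, _ in self.edges:
            if isinstance(self.edge_strength, Mapping):
                out[(parent, child)] = float(self.edge_strength.get((parent, child), self._default_strength()))
            else:
                out[(parent, child)] = float(self.edge_strength)
        return out


@dataclass
class NoiseModel:
    """Replicate-level noise for emulated log-intensities.

    sigma0: baseline log-scale s.d.; trend_slope: log-linear decrease of the
    variance in the group mean (0 = homoscedastic); tech_rho: correlation of
    technical replicates within one biological replicate; effect_size:
    log-fold change corresponding to a +/-1 state.  Defaults mirror typical
    RPPA log-intensity data: sd ~0.2, moderate technical correlation, and
    clearly resolvable (5 sigma) differential effects.
    """

    sigma0: float = 0.2
    trend_slope: float = 0.15
    tech_rho: float = 0.5
    effect_size: float = 1.0
    n_bio: int = 3
    n_tech: int = 3

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ConfigurationError("sigma0 must be > 0")
        if not 0.0 <= self.tech_rho < 1.0:
            raise ConfigurationError("tech_rho must lie in [0, 1)")
        if self.effect_size <= 0:
            raise ConfigurationError("effect_size must be > 0")


def make_ground_truth_model(spec: GroundTruthSpec) -> DBNModel:
    """Instantiate the DBN whose CPTs realize a planted edge specification.

    Combination rule for multiple parents: the child's target state is the
    sign of the signed sum of parent states, plus +1 for every active
    stimulation parent; the target state receives the mean strength of the
    contributing edges and the remaining mass is split over the other two
    states.  A node with no molecule parents and no active stimulation is
    uniform.  Context only tags the measurement modality: CPTs are shared
    across contexts.  The t=0 distribution is uniform.
    """
    strengths = spec._strengths()
    parent_sets: dict[str, list[str]] = {m: [] for m in spec.node_names}
    signs: dict[tuple[str, str], int] = {}
    for parent, child, sign in spec.edges:
        if parent not in parent_sets[child]:
            parent_sets[child].append(parent)
        signs[(parent, child)] = sign
    structure = DBNStructure(
        spec.node_names,
        {m: tuple(sorted(v)) for m, v in parent_sets.items()},
        stim_map=spec.stim_map,
        has_context=True,
    )
    default_strength = spec._default_strength()
    cpts = CPTSet()
    for m in structure.molecules:
        parents = structure.parent_sets[m]
        fixed = structure.fixed_parents(m)
        cards = structure.fixed_cardinalities(m)
        nf = structure.n_fixed_cfg(m)
        npa = N_STATES ** len(parents)
        trans = np.empty((nf, npa, N_STATES))
        for f in range(nf):
            # decode stim values out of the mixed-radix fixed index
            vals, rem = {}, f
            for name, card in zip(reversed(fixed), reversed(cards)):
                vals[name] = rem % card
                rem //= card
            stim_on = [s for s in STIM_NODES if vals.get(s, 0) == 1]
            for pa in range(npa):
                # decode parent states (base 3, most significant = first parent)
                states, rem2 = {}, pa
                for p in reversed(parents):
                    states[p] = rem2 % N_STATES - 1
                    rem2 //= N_STATES
                total = sum(signs[(p, m)] * states[p] for p in parents)
                used = [strengths[(p, m)] for p in parents]
                for _ in stim_on:
                    total += 1
                    used.append(default_strength)
                if not used:
                    trans[f, pa] = 1.0 / N_STATES
                else:
                    target = int(np.sign(total))
                    strength = float(np.mean(used))
                    row = np.full(N_STATES, (1.0 - strength) / 2.0)
                    row[target + 1] = strength
                    trans[f, pa] = row
        init = np.full((nf, N_STATES), 1.0 / N_STATES)
        cpts[m] = NodeCPT(fixed, parents, np.clip(trans, 1e-12, None), init)
    # renormalize after the clip guard (only matters for strength exactly 0/1)
    for cpt in cpts.values():
        cpt.trans /= cpt.trans.sum(axis=-1, keepdims=True)
    return DBNModel(structure, cpts)


def sample_time_series(
    model: DBNModel,
    condition: str | Mapping[str, int] = CONTROL_CONDITION,
    context: str | None = None,
    T: int = 14,
    seed: int | np.random.Generator = 0,
    initial_states: Mapping[str, int] | None = None,
) -> TrinarySeries:
    """Forward-sample one trinary series (see :func:`dbn_core.forward_sample`)."""
    return forward_sample(model, condition, context, T, seed, initial_states)


def sample_study_series(
    model: DBNModel,
    seed: int | np.random.Generator = 0,
    T: int = 14,
    include_controls: bool = False,
    initial_states: Mapping[str, int] | None = None,
) -> list[TrinarySeries]:
    """Sample the nine study-shaped series (plus optional per-context controls).

    Nine series = {cytoplasm, nucleus} x {EGF, SHH, EGF+SHH} for protein and
    {EGF, GLI, EGF+GLI} for transcript, each of length ``T`` (default 14).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for context, conditions in STUDY_CONDITIONS.items():
        todo = conditions + ((CONTROL_CONDITION,) if include_controls else ())
        for condition in todo:
            s = forward_sample(model, condition, context, T, rng, initial_states)
            s.name = f"{context}:{condition}"
            out.append(s)
    return out


def _sigma(mu: np.ndarray, noise: NoiseModel, mu_center: float) -> np.ndarray:
    """Mean-variance trend: variance decays log-linearly in the group mean."""
    var = noise.sigma0 ** 2 * np.exp(-noise.trend_slope * (mu - mu_center))
    return np.sqrt(var)


def emulate_expression(
    series_set: Sequence[TrinarySeries],
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
    baselines: Mapping[str, float] | None = None,
    n_antibodies: int = 1,
) -> pd.DataFrame:
    """Replicate-level log-intensities consistent with a set of trinary series.

    Every stimulated series must be accompanied by a control series of the
    same context (the control defines the unperturbed reference level and is
    emitted at its molecule baselines, since the trinary states are defined
    as change *versus control*).  Per molecule/antibody/context/condition/
    time the table holds n_bio x n_tech values (technical replicates only in
    protein contexts):

        control mean + state * effect_size + biological noise + technical noise

    with the biological component shared within a biological replicate so
    that technical replicates correlate at ``tech_rho``, and the noise s.d.
    taken from the mean-variance trend.  Transcript rows carry small
    detection p-values (every probe is treated as expressed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not series_set:
        raise DataError("empty series set")
    contexts = {s.context for s in series_set}
    for ctx in contexts:
        has_control = any(s.context == ctx and s.condition == CONTROL_CONDITION for s in series_set)
        has_stim = any(s.context == ctx and s.condition != CONTROL_CONDITION for s in series_set)
        if has_stim and not has_control:
            raise DataError(f"missing control series for context {ctx!r}")
    molecules = series_set[0].molecules
    if baselines is None:
        base_vals = rng.uniform(7.0, 11.0, size=len(molecules))
        baselines = dict(zip(molecules, base_vals))
    mu_center = float(np.mean([baselines[m] for m in molecules]))
    rows: dict[str, list] = {c: [] for c in EXPRESSION_COLUMNS}
    for series in series_set:
        is_control = series.condition == CONTROL_CONDITION
        is_transcript = series.context == "transcript"
        n_tech = 1 if is_transcript else noise.n_tech
        for mol in molecules:
            states = series.states.loc[mol].to_numpy()
            for a in range(n_antibodies):
                antibody = mol if n_antibodies == 1 else f"{mol}_ab{a + 1}"
                for t in range(series.n_time):
                    state = 0 if is_control else int(states[t])
                    mu = baselines[mol] + state * noise.effect_size
                    sd = float(_sigma(np.asarray(mu), noise, mu_center))
                    sd_bio = sd * np.sqrt(noise.tech_rho)
                    sd_tech = sd * np.sqrt(1.0 - noise.tech_rho)
                    for b in range(noise.n_bio):
                        shared = rng.normal(0.0, sd_bio)
                        for k in range(n_tech):
                            value = mu + shared + rng.normal(0.0, sd_tech)
                            rows["molecule"].append(mol)
                            rows["antibody"].append(antibody)
                            rows["context"].append(series.context)
                            rows["condition"].append(series.condition)
                            rows["time"].append(t)
                            rows["bio_rep"].append(b + 1)
                            rows["tech_rep"].append(k + 1)
                            rows["value"].append(value)
                            rows["detection_p"].append(
                                float(rng.uniform(0.0, 1e-4)) if is_transcript else np.nan
                            )
    return pd.DataFrame(rows)


#: Planted literature-consistent transition model used throughout the tests:
#: one identifiable parent per downstream molecule, receptor-level molecules
#: driven by their stimulation nodes, ligand SHH free-running.
STUDY_TRUTH_EDGES: tuple[tuple[str, str], ...] = (
    ("EGFR", "ERK"),
    ("EGFR", "AKT"),
    ("EGFR", "p38"),
    ("ERK", "p70S6K"),
    ("AKT", "CREB"),
    ("p38", "JUN"),
    ("SHH", "PTCH1"),
    ("PTCH1", "GLI2"),
    ("GLI2", "GLI1"),
    ("GLI2", "SUFU"),
)


def study_ground_truth(edge_strength: float = 0.9) -> GroundTruthSpec:
    """The default planted model for study-shaped simulations."""
    return GroundTruthSpec(edges=STUDY_TRUTH_EDGES, edge_strength=edge_strength)


def literature_ground_truth(edge_strength: float = 0.9) -> GroundTruthSpec:
    """A ground truth whose edges are the full packaged literature network.

    Children with several literature parents follow the signed-sum rule, so
    individual edges are partially redundant — deliberately harder to
    identify than :func:`study_ground_truth`, and the right test bed for
    comparing background-knowledge regimes.
    """
    from .structure_learning import load_literature_edges

    return GroundTruthSpec(edges=tuple(sorted(load_literature_edges())), edge_strength=edge_strength)
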