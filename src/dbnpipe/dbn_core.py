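"""Discrete dynamic Bayesian network (DBN) data model.

A DBN here is a pair (graph, parameters) over trinary molecule nodes
(states -1/0/+1 encode significant down-regulation, no change and
up-regulation versus control) plus exogenous design nodes: a three-level
``context`` node (cytoplasmic protein, nuclear protein, transcript) and
binary stimulation nodes (EGF_stim, SHH_stim, GLI_stim) that parent the
receptor-level molecules they perturb.  All learnable edges run from time
slice t-1 to slice t (first-order Markov); nodes are independent at t=0.

This module owns the containers (TrinarySeries, DBNStructure, CPTSet,
TransitionCounts, DBNModel), sufficient-statistic collection, maximum a
posteriori parameter estimation with Dirichlet pseudo-counts, the joint
log-likelihood and ancestral forward sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dbnpipe")

# ---------------------------------------------------------------------------
# Global discrete alphabets
# ---------------------------------------------------------------------------

STATES: tuple[int, ...] = (-1, 0, 1)
N_STATES = 3

CONTEXT_NODE = "context"
CONTEXT_LEVELS: tuple[str, ...] = ("cyt_protein", "nuc_protein", "transcript")

STIM_NODES: tuple[str, ...] = ("EGF_stim", "SHH_stim", "GLI_stim")

#: Which stimulation reaches which molecule: EGF stimulates the EGF receptor,
#: SHH engages its receptors PTCH1 and HHIP, induced GLI1 acts on GLI1 itself.
DEFAULT_STIM_MAP: dict[str, tuple[str, ...]] = {
    "EGF_stim": ("EGFR",),
    "SHH_stim": ("PTCH1", "HHIP"),
    "GLI_stim": ("GLI1",),
}

#: Default 13-molecule panel of the EGFR / sonic hedgehog cross-talk model.
#: Editable: pass your own node list wherever a structure or ground truth is
#: built; nothing below hard-codes these names.
DEFAULT_MOLECULES: tuple[str, ...] = (
    "AKT",
    "CREB",
    "EGFR",
    "ERK",
    "GLI1",
    "GLI2",
    "HHIP",
    "JUN",
    "PTCH1",
    "SHH",
    "SUFU",
    "p38",
    "p70S6K",
)

_TOKEN_TO_STIM = {"EGF": "EGF_stim", "SHH": "SHH_stim", "GLI": "GLI_stim"}

CONTROL_CONDITION = "control"


class DataError(ValueError):
    """Raised when input series/tables violate the discrete data contract."""


class ConfigurationError(ValueError):
    """Raised when a model/structure specification is inconsistent."""


def stim_from_condition(condition: str) -> dict[str, int]:
    """Map a condition label (e.g. ``"EGF+SHH"``) to stimulation-node values.

    ``"control"`` (or empty) switches every stimulation node off.  Tokens are
    ``EGF``, ``SHH`` and ``GLI``, combined with ``+``.
    """
    values = {s: 0 for s in STIM_NODES}
    if condition in (CONTROL_CONDITION, "", None):
        return values
    for token in str(condition).split("+"):
        token = token.strip()
        if token not in _TOKEN_TO_STIM:
            raise DataError(f"unknown stimulation token {token!r} in condition {condition!r}")
        values[_TOKEN_TO_STIM[token]] = 1
    return values


# ---------------------------------------------------------------------------
# Trinary time series
# ---------------------------------------------------------------------------


@dataclass
class TrinarySeries:
    """One discretized time course: molecules x time, states in {-1, 0, 1}.

    ``context`` / ``condition`` carry the experimental design; stimulation
    node values are derived from the condition and constant over the series
    (a sustained stimulation).  ``context`` may be ``None`` for bare test
    models without design nodes.
    """

    states: pd.DataFrame
    condition: str = CONTROL_CONDITION
    context: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.states = self.states.astype(np.int8)
        bad = ~self.states.isin(STATES)
        if bad.to_numpy().any():
            raise DataError("series states must lie in {-1, 0, 1}")
        if self.context is not None and self.context not in CONTEXT_LEVELS:
            raise DataError(f"unknown context {self.context!r}")
        self.states.columns = range(self.states.shape[1])

    @property
    def molecules(self) -> tuple[str, ...]:
        return tuple(self.states.index)

    @property
    def n_time(self) -> int:
        return self.states.shape[1]

    @property
    def stim(self) -> dict[str, int]:
        return stim_from_condition(self.condition)

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"#@ condition\t{self.condition}\n")
            fh.write(f"#@ context\t{self.context if self.context is not None else ''}\n")
            fh.write(f"#@ name\t{self.name}\n")
            self.states.to_csv(fh, sep="\t", index_label="molecule")

    @classmethod
    def from_tsv(cls, path) -> "TrinarySeries":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#@ "):
                key, _, val = line[3:].rstrip("\n").partition("\t")
                meta[key] = val
            elif not line.startswith("#"):
                body.append(line)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="molecule")
        df.index.name = None
        return cls(
            states=df,
            condition=meta.get("condition", CONTROL_CONDITION),
            context=meta.get("context") or None,
            name=meta.get("name", ""),
        )


def check_series_compatible(series_set: Sequence[TrinarySeries]) -> tuple[str, ...]:
    """All series must share one molecule set; returns it."""
    if not series_set:
        raise DataError("empty series set")
    mols = series_set[0].molecules
    for s in series_set[1:]:
        if s.molecules != mols:
            raise DataError("inconsistent node sets across series")
    return mols


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: str  # molecule | context | stimulation
    cardinality: int

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise ConfigurationError("node cardinality must be >= 2")


@dataclass
class DBNStructure:
    """Per-molecule parent sets over slice t-1 plus fixed design wiring.

    ``parent_sets`` hold the *learnable* molecule->molecule edges (self-loops
    allowed).  The fixed wiring — context parents every molecule, each
    stimulation node parents its targets — is implied by ``has_context`` and
    ``stim_map`` and is never part of ``parent_sets``.
    """

    molecules: tuple[str, ...]
    parent_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    stim_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    has_context: bool = True

    def __post_init__(self) -> None:
        self.molecules = tuple(self.molecules)
        known = set(self.molecules)
        cleaned = {}
        for mol in self.molecules:
            parents = tuple(sorted(self.parent_sets.get(mol, ())))
            for p in parents:
                if p not in known:
                    raise ConfigurationError(f"unknown parent {p!r} of {mol!r}")
            cleaned[mol] = parents
        self.parent_sets = cleaned
        self.stim_map = {k: tuple(v) for k, v in self.stim_map.items()}
        for stim, targets in self.stim_map.items():
            if stim not in STIM_NODES:
                raise ConfigurationError(f"unknown stimulation node {stim!r}")
            for t in targets:
                if t not in known:
                    raise ConfigurationError(f"stimulation target {t!r} is not a molecule node")

    # -- node bookkeeping ---------------------------------------------------

    @classmethod
    def bare(cls, molecules: Iterable[str], parent_sets: Mapping[str, Iterable[str]] | None = None) -> "DBNStructure":
        """A molecules-only structure (no context/stimulation wiring)."""
        ps = {m: tuple(v) for m, v in (parent_sets or {}).items()}
        return cls(tuple(molecules), ps, stim_map={}, has_context=False)

    def nodes(self) -> list[NodeSpec]:
        out = [NodeSpec(m, "molecule", N_STATES) for m in self.molecules]
        if self.has_context:
            out.append(NodeSpec(CONTEXT_NODE, "context", len(CONTEXT_LEVELS)))
        out.extend(NodeSpec(s, "stimulation", 2) for s in STIM_NODES if s in self.stim_map)
        return out

    def fixed_parents(self, molecule: str) -> tuple[str, ...]:
        """Design parents of a molecule: context first, then stim nodes."""
        fixed: list[str] = []
        if self.has_context:
            fixed.append(CONTEXT_NODE)
        for stim in STIM_NODES:
            if molecule in self.stim_map.get(stim, ()):
                fixed.append(stim)
        return tuple(fixed)

    def fixed_cardinalities(self, molecule: str) -> tuple[int, ...]:
        return tuple(
            len(CONTEXT_LEVELS) if f == CONTEXT_NODE else 2 for f in self.fixed_parents(molecule)
        )

    def n_fixed_cfg(self, molecule: str) -> int:
        return int(np.prod(self.fixed_cardinalities(molecule), dtype=int)) if self.fixed_parents(molecule) else 1

    def fixed_cfg_index(self, molecule: str, context: str | None, stim: Mapping[str, int]) -> int:
        idx = 0
        for f, card in zip(self.fixed_parents(molecule), self.fixed_cardinalities(molecule)):
            if f == CONTEXT_NODE:
                if context is None:
                    raise DataError(f"series lacks a context but structure wires {CONTEXT_NODE}")
                val = CONTEXT_LEVELS.index(context)
            else:
                val = int(stim[f])
            idx = idx * card + val
        return idx

    def learnable_edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c in self.molecules for p in self.parent_sets[c]]

    # -- serialization ------------------------------------------------------

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#@ molecules\t{','.join(self.molecules)}\n")
            fh.write(f"#@ has_context\t{int(self.has_context)}\n")
            stim_repr = ";".join(f"{s}:{','.join(t)}" for s, t in self.stim_map.items())
            fh.write(f"#@ stim_map\t{stim_repr}\n")
            for parent, child in self.learnable_edges():
                fh.write(f"{parent}\t->\t{child}\n")

    @classmethod
    def from_sif(cls, path) -> "DBNStructure":
        meta: dict[str, str] = {}
        edges: list[tuple[str, str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#@ "):
                    key, _, val = line[3:].partition("\t")
                    meta[key] = val
                elif line and not line.startswith("#"):
                    parent, _, child = line.split("\t")
                    edges.append((parent, child))
        molecules = tuple(meta["molecules"].split(","))
        stim_map = {}
        if meta.get("stim_map"):
            for item in meta["stim_map"].split(";"):
                stim, _, targets = item.partition(":")
                stim_map[stim] = tuple(targets.split(","))
        parent_sets: dict[str, list[str]] = {m: [] for m in molecules}
        for parent, child in edges:
            parent_sets[child].append(parent)
        return cls(
            molecules,
            {m: tuple(v) for m, v in parent_sets.items()},
            stim_map=stim_map,
            has_context=bool(int(meta.get("has_context", "1"))),
        )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class NodeCPT:
    """Conditional probability tables for one molecule node.

    ``trans`` has shape (n_fixed_cfg, 3**n_parents, 3):
    P(x(t) | fixed design values, molecule parent states at t-1).
    ``init`` has shape (n_fixed_cfg, 3): the t=0 marginal (nodes are
    independent at time zero, conditioned on the design only).
    """

    fixed_parents: tuple[str, ...]
    parents: tuple[str, ...]
    trans: np.ndarray
    init: np.ndarray

    def validate(self, atol: float = 1e-12) -> None:
        for arr in (self.trans, self.init):
            if np.any(arr <= 0):
                raise ConfigurationError("CPT entries must be strictly positive after smoothing")
            if np.max(np.abs(arr.sum(axis=-1) - 1.0)) > atol:
                raise ConfigurationError("CPT rows must sum to 1")


class CPTSet(dict):
    """Mapping node name -> NodeCPT with validation and JSON round-trip."""

    def validate(self) -> None:
        for cpt in self.values():
            cpt.validate()

    def to_json(self, path) -> None:
        payload = {
            name: {
                "fixed_parents": list(cpt.fixed_parents),
                "parents": list(cpt.parents),
                "trans": cpt.trans.tolist(),
                "init": cpt.init.tolist(),
            }
            for name, cpt in self.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CPTSet":
        with open(path) as fh:
            payload = json.load(fh)
        out = cls()
        for name, d in payload.items():
            out[name] = NodeCPT(
                tuple(d["fixed_parents"]),
                tuple(d["parents"]),
                np.asarray(d["trans"], dtype=float),
                np.asarray(d["init"], dtype=float),
            )
        return out


@dataclass
class DBNModel:
    """A structure together with its conditional probability tables."""

    structure: DBNStructure
    cpts: CPTSet

    def __post_init__(self) -> None:
        missing = set(self.structure.molecules) - set(self.cpts)
        if missing:
            raise ConfigurationError(f"CPTs missing for nodes {sorted(missing)}")
        self.cpts.validate()


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------


def _parent_config_index(states_prev: np.ndarray, parent_cols: Sequence[int]) -> np.ndarray:
    """Mixed-radix index of parent states (-1/0/1 -> 0/1/2), base 3."""
    idx = np.zeros(states_prev.shape[0], dtype=np.int64)
    for col in parent_cols:
        idx = idx * N_STATES + (states_prev[:, col] + 1)
    return idx


@dataclass
class TransitionCounts:
    """Aligned transition data plus per-node count tables.

    Stores both the raw (t-1, t) state pairs of every consecutive time pair in
    every training series — so contingency tables for *arbitrary* candidate
    parent sets can be built during structure search — and, lazily, the dense
    count tables for the structure's own parent sets used by
    :func:`learn_parameters`.
    """

    structure: DBNStructure
    prev: np.ndarray  # (M, n_molecules) states at t-1
    curr: np.ndarray  # (M, n_molecules) states at t
    fixed_idx: dict[str, np.ndarray]  # per molecule: design config per row
    init_states: np.ndarray  # (n_series, n_molecules) states at t=0
    init_fixed_idx: dict[str, np.ndarray]  # per molecule: design config per series

    @property
    def n_transitions(self) -> int:
        return self.prev.shape[0]

    def _col(self, molecule: str) -> int:
        return self.structure.molecules.index(molecule)

    def table(self, molecule: str) -> np.ndarray:
        """Counts (n_fixed_cfg, 3**n_parents, 3) for the structure's parents."""
        parents = self.structure.parent_sets[molecule]
        nf = self.structure.n_fixed_cfg(molecule)
        npa = N_STATES ** len(parents)
        pa_idx = _parent_config_index(self.prev, [self._col(p) for p in parents])
        child = self.curr[:, self._col(molecule)] + 1
        flat = (self.fixed_idx[molecule] * npa + pa_idx) * N_STATES + child
        counts = np.bincount(flat, minlength=nf * npa * N_STATES)
        return counts.reshape(nf, npa, N_STATES)

    def init_table(self, molecule: str) -> np.ndarray:
        nf = self.structure.n_fixed_cfg(molecule)
        child = self.init_states[:, self._col(molecule)] + 1
        flat = self.init_fixed_idx[molecule] * N_STATES + child
        return np.bincount(flat, minlength=nf * N_STATES).reshape(nf, N_STATES)

    def contingency(self, child: str, parents: Sequence[str]) -> np.ndarray:
        """Counts (n_fixed_cfg(child), 3**k, 3) for an arbitrary candidate set.

        Used by structure search: the design (context/stimulation) parents of
        the child stratify the table; candidate parents index the middle axis.
        """
        nf = self.structure.n_fixed_cfg(child)
        npa = N_STATES ** len(parents)
        pa_idx = _parent_config_index(self.prev, [self._col(p) for p in parents])
        ch = self.curr[:, self._col(child)] + 1
        flat = (self.fixed_idx[child] * npa + pa_idx) * N_STATES + ch
        return np.bincount(flat, minlength=nf * npa * N_STATES).reshape(nf, npa, N_STATES)


def collect_transitions(series_set: Sequence[TrinarySeries], structure: DBNStructure) -> TransitionCounts:
    """Accumulate all consecutive (t-1, t) state pairs of all series.

    A series of length T contributes T-1 transitions per node; stimulation and
    context values are constant within a series and enter each row's design
    configuration.
    """
    mols = check_series_compatible(series_set)
    if mols != structure.molecules:
        raise DataError("series molecule set does not match the structure")
    prev_blocks, curr_blocks = [], []
    fixed_rows: dict[str, list[np.ndarray]] = {m: [] for m in mols}
    init_rows: list[np.ndarray] = []
    init_fixed: dict[str, list[int]] = {m: [] for m in mols}
    for s in series_set:
        arr = s.states.loc[list(mols)].to_numpy(dtype=np.int8).T  # (T, n_mol)
        init_rows.append(arr[0])
        n_tr = arr.shape[0] - 1
        if n_tr > 0:
            prev_blocks.append(arr[:-1])
            curr_blocks.append(arr[1:])
        for m in mols:
            f = structure.fixed_cfg_index(m, s.context, s.stim)
            init_fixed[m].append(f)
            if n_tr > 0:
                fixed_rows[m].append(np.full(n_tr, f, dtype=np.int64))
    empty = np.zeros((0, len(mols)), dtype=np.int8)
    return TransitionCounts(
        structure=structure,
        prev=np.concatenate(prev_blocks, axis=0) if prev_blocks else empty,
        curr=np.concatenate(curr_blocks, axis=0) if curr_blocks else empty,
        fixed_idx={
            m: (np.concatenate(v) if v else np.zeros(0, dtype=np.int64)) for m, v in fixed_rows.items()
        },
        init_states=np.stack(init_rows, axis=0),
        init_fixed_idx={m: np.asarray(v, dtype=np.int64) for m, v in init_fixed.items()},
    )


def learn_parameters(counts: TransitionCounts, pseudo: float = 1.0) -> CPTSet:
    """MAP estimate with a Dirichlet pseudo-count on every CPT cell.

    P(x | pa) = (N_{x,pa} + pseudo) / (N_{.,pa} + pseudo * 3); unseen parent
    configurations therefore fall back to the uniform distribution.  The t=0
    marginals are smoothed the same way.
    """
    if pseudo <= 0:
        raise ConfigurationError("pseudo-count must be > 0")
    structure = counts.structure
    cpts = CPTSet()
    for m in structure.molecules:
        tab = counts.table(m).astype(float)
        trans = (tab + pseudo) / (tab.sum(axis=-1, keepdims=True) + pseudo * N_STATES)
        itab = counts.init_table(m).astype(float)
        init = (itab + pseudo) / (itab.sum(axis=-1, keepdims=True) + pseudo * N_STATES)
        cpts[m] = NodeCPT(structure.fixed_parents(m), structure.parent_sets[m], trans, init)
    cpts.validate()
    return cpts


def fit_model(series_set: Sequence[TrinarySeries], structure: DBNStructure, pseudo: float = 1.0) -> DBNModel:
    """Convenience: collect transitions and learn parameters in one call."""
    return DBNModel(structure, learn_parameters(collect_transitions(series_set, structure), pseudo))


# ---------------------------------------------------------------------------
# Likelihood and sampling
# ---------------------------------------------------------------------------


def joint_log_prob(model: DBNModel, series: TrinarySeries) -> float:
    """log p(x(0), ..., x(T)) under the factorized first-order Markov model."""
    st = model.structure
    if series.molecules != st.molecules:
        raise DataError("series molecule set does not match the model")
    arr = series.states.to_numpy(dtype=np.int8).T  # (T, n_mol)
    if np.isnan(series.states.to_numpy(dtype=float)).any():
        raise DataError("joint_log_prob requires a fully observed series")
    total = 0.0
    cols = {m: i for i, m in enumerate(st.molecules)}
    for m in st.molecules:
        cpt = model.cpts[m]
        f = st.fixed_cfg_index(m, series.context, series.stim)
        total += float(np.log(cpt.init[f, arr[0, cols[m]] + 1]))
        if arr.shape[0] > 1:
            pa_idx = _parent_config_index(arr[:-1], [cols[p] for p in cpt.parents])
            total += float(np.log(cpt.trans[f, pa_idx, arr[1:, cols[m]] + 1]).sum())
    return total


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw, one per row; returns indices 0..2."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])[:, None]
    return (u > cum[:, :-1]).sum(axis=1)


def forward_sample(
    model: DBNModel,
    condition: str | Mapping[str, int] = CONTROL_CONDITION,
    context: str | None = None,
    T: int = 14,
    seed: int | np.random.Generator = 0,
    initial_states: Mapping[str, int] | None = None,
) -> TrinarySeries:
    """Ancestral (slice-by-slice) sampling of a length-T series.

    ``initial_states`` clamps chosen nodes at t=0 (the stimulation persists
    for the whole time course; context is constant).  Reproducible: the same
    seed yields the same series.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    st = model.structure
    if isinstance(condition, str):
        cond_label, stim = condition, stim_from_condition(condition)
    else:
        stim = {s: int(condition.get(s, 0)) for s in STIM_NODES}
        on = [tok for tok, s in _TOKEN_TO_STIM.items() if stim[s]]
        cond_label = "+".join(on) if on else CONTROL_CONDITION
    mols = st.molecules
    cols = {m: i for i, m in enumerate(mols)}
    fixed = {m: st.fixed_cfg_index(m, context, stim) for m in mols}
    out = np.zeros((T, len(mols)), dtype=np.int8)
    trans_cum = {m: np.cumsum(model.cpts[m].trans[fixed[m]], axis=-1) for m in mols}
    init_cum = {m: np.cumsum(model.cpts[m].init[fixed[m]]) for m in mols}
    pa_cols = {m: [cols[p] for p in model.cpts[m].parents] for m in mols}
    for m in mols:
        if initial_states is not None and m in initial_states:
            out[0, cols[m]] = initial_states[m]
        else:
            out[0, cols[m]] = min(int(np.searchsorted(init_cum[m], rng.random(), side="right")), N_STATES - 1) - 1
    for t in range(1, T):
        prev = out[t - 1 : t]
        for m in mols:
            pa_idx = 0
            for c in pa_cols[m]:
                pa_idx = pa_idx * N_STATES + int(prev[0, c]) + 1
            cum = trans_cum[m][pa_idx]
            out[t, cols[m]] = min(int(np.searchsorted(cum, rng.random(), side="right")), N_STATES - 1) - 1
    df = pd.DataFrame(out.T, index=list(mols))
    return TrinarySeries(states=df, condition=cond_label, context=context)
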