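"""Per-node exact structure search with the mutual-information-test score.

The MIT score of a child/parent-set family is

    2 * N * MI(child; parents)  -  sum_j chi2_{1-alpha_j}(l_j)

where N is the number of observed transitions, MI is plug-in mutual
information (nats) and the j-th penalty is the critical value of the
chi-square independence test at type-I error rate ``alpha_j`` with

    l_j = (r_child - 1) (r_j - 1) * prod_{k<j} r_k * prod_f r_f,

parents ordered by decreasing cardinality (name-lexicographic ties) and the
final factor running over the child's *fixed* design parents (context,
stimulation).  Those design parents always condition the counts — they
encode the experimental design, not hypotheses — so the mutual information
is conditional on them and the chain-rule degrees of freedom pick up their
configuration count; with no fixed parents the expression is the classical
MIT penalty.  The score is decomposable, so each molecule's optimal parent
set (over subsets of the allowed candidates, up to ``max_parents``) can be
found independently; all learnable edges cross time slices, which makes
acyclicity automatic.

Background-knowledge regimes: ``strong`` restricts candidates to literature
parents, ``weak`` admits every molecule but relaxes the type-I rate for
literature edges by ``weak_factor``, ``none`` is fully data-driven.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from .dbn_core import (
    CONTROL_CONDITION,
    DEFAULT_STIM_MAP,
    ConfigurationError,
    DataError,
    DBNStructure,
    N_STATES,
    TransitionCounts,
    TrinarySeries,
    check_series_compatible,
    collect_transitions,
)

logger = logging.getLogger("dbnpipe")

__all__ = [
    "PriorKnowledge",
    "ScoreConfig",
    "load_literature_edges",
    "mutual_information",
    "mit_family_score",
    "optimal_parents",
    "learn_structure",
]


def load_literature_edges(path=None) -> frozenset[tuple[str, str]]:
    """Read a SIF-like edge list (``parent<TAB>-><TAB>child`` per line).

    Without ``path`` the packaged default literature network is used.
    """
    if path is None:
        text = resources.files("dbnpipe").joinpath("data/literature_edges.sif").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    edges = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DataError(f"malformed SIF line: {line!r}")
        edges.add((parts[0], parts[2]))
    return frozenset(edges)


@dataclass
class ScoreConfig:
    alpha: float = 0.10  # expected proportion of false-positive edges
    max_parents: int = 4
    self_loops: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.max_parents < 0:
            raise ConfigurationError("max_parents must be >= 0")


@dataclass
class PriorKnowledge:
    mode: str = "strong"  # strong | weak | none
    literature_edges: frozenset[tuple[str, str]] = field(default_factory=load_literature_edges)
    weak_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("strong", "weak", "none"):
            raise ConfigurationError(f"unknown prior mode {self.mode!r}")
        if self.weak_factor < 1.0:
            raise ConfigurationError("weak_factor must be >= 1")
        self.literature_edges = frozenset(tuple(e) for e in self.literature_edges)

    def edge_alpha(self, parent: str, child: str, alpha: float) -> float:
        """Type-I error rate for one edge; relaxed for literature edges in weak mode."""
        if self.mode == "weak" and (parent, child) in self.literature_edges:
            return min(self.weak_factor * alpha, 1.0)
        return alpha

    def candidates(self, child: str, molecules: Sequence[str], cfg: ScoreConfig) -> tuple[str, ...]:
        if self.mode == "strong":
            cands = {p for (p, c) in self.literature_edges if c == child and p in molecules}
        else:
            cands = set(molecules) - {child}
        if cfg.self_loops:
            cands.add(child)
        else:
            cands.discard(child)
        return tuple(sorted(cands))


@lru_cache(maxsize=4096)
def _chi2_quantile(alpha: float, df: int) -> float:
    if alpha >= 1.0:
        return 0.0
    return float(chi2.ppf(1.0 - alpha, df))


def mutual_information(joint_counts: np.ndarray) -> float:
    """Plug-in mutual information (nats) of a child x parent-config table.

    0 * log 0 is taken as 0.  Raises on an empty table.
    """
    t = np.asarray(joint_counts, dtype=float)
    if t.size == 0 or t.sum() <= 0:
        raise DataError("empty contingency table")
    return _stratified_mi(t.reshape(1, *t.shape))[0]


def _stratified_mi(table: np.ndarray) -> tuple[float, float]:
    """(conditional MI given the stratum axis, total N) for a (F, A, B) table."""
    n = table.sum()
    nf = table.sum(axis=(1, 2))
    na = table.sum(axis=2)
    nb = table.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * (
            np.log(table)
            + np.log(nf)[:, None, None]
            - np.log(na)[:, :, None]
            - np.log(nb)[:, None, :]
        )
    return float(np.nansum(terms) / n), float(n)


def _ordered(parents: Iterable[str]) -> tuple[str, ...]:
    # all molecule nodes share cardinality 3, so "decreasing cardinality,
    # ties by name" reduces to name order
    return tuple(sorted(parents, key=lambda p: (-N_STATES, p)))


def _penalty(child: str, ordered_parents: Sequence[str], n_fixed: int, cfg: ScoreConfig, prior: PriorKnowledge) -> float:
    pen, cum = 0.0, 1
    for p in ordered_parents:
        df = (N_STATES - 1) * (N_STATES - 1) * cum * n_fixed
        pen += _chi2_quantile(prior.edge_alpha(p, child, cfg.alpha), df)
        cum *= N_STATES
    return pen


def mit_family_score(
    child: str,
    parents: Iterable[str],
    counts: TransitionCounts,
    cfg: ScoreConfig,
    prior: PriorKnowledge,
) -> float:
    """Penalized-MI family score; the empty parent set scores exactly 0."""
    ordered = _ordered(parents)
    if len(ordered) > cfg.max_parents:
        raise ConfigurationError(
            f"{len(ordered)} parents exceed max_parents={cfg.max_parents}"
        )
    if not ordered:
        return 0.0
    table = counts.contingency(child, ordered)
    mi, n = _stratified_mi(np.transpose(table, (0, 2, 1)))  # child x parent-configs
    n_fixed = counts.structure.n_fixed_cfg(child)
    return 2.0 * n * mi - _penalty(child, ordered, n_fixed, cfg, prior)


def optimal_parents(
    child: str,
    candidates: Iterable[str],
    counts: TransitionCounts,
    cfg: ScoreConfig,
    prior: PriorKnowledge,
) -> tuple[str, ...]:
    """Argmax of the family score over candidate subsets of size <= max_parents.

    Exhaustive enumeration with a sound penalty bound: the achievable reward
    is at most 2N * H(child | fixed design), so any subset whose penalty
    reaches that bound scores <= 0 and cannot beat the empty set.  Ties go to
    the smaller set, then to lexicographic order — the result is identical
    to unpruned brute force.
    """
    cands = tuple(sorted(set(candidates)))
    if not cands:
        return ()
    st = counts.structure
    n_fixed = st.n_fixed_cfg(child)
    # achievable upper bound on 2 N MI: conditional entropy of the child
    marg = counts.contingency(child, ())  # (F, 1, 3)
    _, n_total = _stratified_mi(marg)
    if n_total == 0:
        return ()
    nf = marg[:, 0, :].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(marg[:, 0, :] * np.log(marg[:, 0, :] / nf[:, None])) / n_total
    bound = 2.0 * n_total * h

    # hot-path arrays shared across subsets
    cols = {p: st.molecules.index(p) for p in cands}
    prev = counts.prev
    fixed = counts.fixed_idx[child]
    y = counts.curr[:, st.molecules.index(child)].astype(np.int64) + 1
    cand_states = {p: (prev[:, cols[p]].astype(np.int64) + 1) for p in cands}

    best_score, best_set = 0.0, ()
    max_k = min(cfg.max_parents, len(cands))
    for k in range(1, max_k + 1):
        for subset in combinations(cands, k):
            ordered = subset  # cands sorted lexicographically == score order
            pen = _penalty(child, ordered, n_fixed, cfg, prior)
            if pen >= bound:
                continue
            idx = fixed
            for p in ordered:
                idx = idx * N_STATES + cand_states[p]
            npa = N_STATES ** k
            flat = idx * N_STATES + y
            table = np.bincount(flat, minlength=n_fixed * npa * N_STATES).reshape(
                n_fixed, npa, N_STATES
            )
            mi, n = _stratified_mi(np.transpose(table, (0, 2, 1)))
            score = 2.0 * n * mi - pen
            if score > best_score:
                best_score, best_set = score, ordered
    return tuple(best_set)


def learn_structure(
    series_set: Sequence[TrinarySeries],
    cfg: ScoreConfig,
    prior: PriorKnowledge,
    stim_map=None,
    has_context: bool | None = None,
) -> DBNStructure:
    """Assemble the full structure: fixed wiring plus per-node optimal parents.

    The design wiring (context parents every molecule; each stimulation node
    its targets) is installed unconditionally; molecule parent sets are
    optimized per node, which is exact because the score decomposes and all
    learnable edges cross slices.
    """
    molecules = check_series_compatible(series_set)
    if not any(s.n_time >= 2 for s in series_set):
        raise DataError("need at least one series with >= 2 time points")
    if has_context is None:
        has_context = series_set[0].context is not None
    if stim_map is None:
        if any(s.condition != CONTROL_CONDITION for s in series_set):
            stim_map = {
                s: tuple(t for t in targets if t in molecules)
                for s, targets in DEFAULT_STIM_MAP.items()
            }
            stim_map = {s: t for s, t in stim_map.items() if t}
        else:
            stim_map = {}
    skeleton = DBNStructure(molecules, {}, stim_map=stim_map, has_context=has_context)
    counts = collect_transitions(series_set, skeleton)
    parent_sets = {
        m: optimal_parents(m, prior.candidates(m, molecules, cfg), counts, cfg, prior)
        for m in molecules
    }
    return DBNStructure(molecules, parent_sets, stim_map=stim_map, has_context=has_context)
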