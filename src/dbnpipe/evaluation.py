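"""Model validation: leave-one-series-out prediction and parametric bootstrap.

Leave-one-out: each of the nine study series is held out in turn, a DBN
(structure + parameters) is learned from the remaining series, the target
molecules are hidden in the held-out series and predicted by likelihood
weighting, and the most-probable states are compared against the held-out
observations.  Accuracy counts all time points of the held-out series,
including t=0 (the initial-slice model predicts it too).

Parametric bootstrap: a DBN is fitted to the complete data; B synthetic
datasets of identical shape (same series count, lengths, contexts and
stimulation assignments) are forward-sampled from it and structure learning
is re-run on each.  The relative frequency with which each learnable edge
reappears measures how stably the data of this size support it; edges above
a cutoff (default 50%) are reported as stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dbn_core import (
    ConfigurationError,
    N_STATES,
    TrinarySeries,
    check_series_compatible,
    fit_model,
    forward_sample,
)
from .inference import EvidenceSeries, map_state, predict_posterior
from .structure_learning import PriorKnowledge, ScoreConfig, learn_structure

__all__ = [
    "ValidationResult",
    "EdgeFrequencyTable",
    "DEFAULT_TARGETS",
    "loo_validate",
    "parametric_bootstrap",
    "stable_edges",
    "write_edges_dot",
]

#: Key proliferation-associated molecules predicted in the validation:
#: the transcription factors GLI1, CREB and JUN, and the kinase p70S6K.
DEFAULT_TARGETS: tuple[str, ...] = ("GLI1", "CREB", "JUN", "p70S6K")


@dataclass
class ValidationResult:
    """Per-fold / per-target accuracies plus the pooled (joint) accuracy."""

    per_fold: pd.DataFrame  # columns: fold, target, accuracy
    joint: pd.DataFrame  # columns: fold, accuracy (all targets pooled)
    targets: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        """Median and quartiles across folds, per target and pooled."""
        rows = []
        for target, grp in self.per_fold.groupby("target"):
            acc = grp["accuracy"]
            rows.append((target, acc.median(), acc.quantile(0.25), acc.quantile(0.75)))
        acc = self.joint["accuracy"]
        rows.append(("all", acc.median(), acc.quantile(0.25), acc.quantile(0.75)))
        return pd.DataFrame(rows, columns=["target", "median", "q25", "q75"])


@dataclass
class EdgeFrequencyTable:
    """Bootstrap support per learnable (molecule -> molecule) edge."""

    frequencies: pd.DataFrame  # columns: parent, child, frequency
    B: int


def _prior_marginals(train: Sequence[TrinarySeries], targets: Sequence[str]) -> dict[str, np.ndarray]:
    """Pooled training-state frequencies, used only for -1/+1 tie-breaks."""
    out = {}
    for m in targets:
        vals = np.concatenate([s.states.loc[m].to_numpy() for s in train])
        out[m] = np.bincount(vals + 1, minlength=N_STATES) / vals.size
    return out


def loo_validate(
    series_set: Sequence[TrinarySeries],
    cfg: ScoreConfig,
    prior: PriorKnowledge,
    targets: Sequence[str] = DEFAULT_TARGETS,
    N: int = 1000,
    seed: int = 0,
    pseudo: float = 1.0,
) -> ValidationResult:
    """Leave-one-series-out validation of posterior state predictions."""
    mols = check_series_compatible(series_set)
    if len(series_set) < 2:
        raise ConfigurationError("need at least 2 series for leave-one-out validation")
    missing = set(targets) - set(mols)
    if missing:
        raise ConfigurationError(f"targets absent from the node set: {sorted(missing)}")
    fold_seeds = np.random.SeedSequence(seed).spawn(len(series_set))
    rows, joint_rows = [], []
    for fold, held_out in enumerate(series_set):
        train = [s for i, s in enumerate(series_set) if i != fold]
        structure = learn_structure(train, cfg, prior)
        model = fit_model(train, structure, pseudo)
        evidence = EvidenceSeries.from_series(held_out, hide=targets)
        posterior = predict_posterior(
            model, evidence, N=N, seed=np.random.default_rng(fold_seeds[fold])
        )
        calls = map_state(posterior, _prior_marginals(train, targets))
        n_match_total = 0
        for target in targets:
            truth = held_out.states.loc[target].to_numpy()
            pred = calls.loc[target].to_numpy()
            n_match = int((pred == truth).sum())
            rows.append((fold, target, n_match / truth.size))
            n_match_total += n_match
        joint_rows.append((fold, n_match_total / (held_out.n_time * len(targets))))
    return ValidationResult(
        per_fold=pd.DataFrame(rows, columns=["fold", "target", "accuracy"]),
        joint=pd.DataFrame(joint_rows, columns=["fold", "accuracy"]),
        targets=tuple(targets),
    )


def parametric_bootstrap(
    series_set: Sequence[TrinarySeries],
    cfg: ScoreConfig,
    prior: PriorKnowledge,
    B: int = 100,
    seed: int = 0,
    pseudo: float = 1.0,
) -> EdgeFrequencyTable:
    """Edge confidence by refitting on B model-sampled datasets.

    Re-learning uses the same score configuration and background-knowledge
    regime as the original fit, so frequencies measure data support within
    the chosen hypothesis space.  Fixed design wiring is not counted.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    structure = learn_structure(series_set, cfg, prior)
    model = fit_model(series_set, structure, pseudo)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edge_counts: dict[tuple[str, str], int] = {}
    for _ in range(B):
        sampled = [
            forward_sample(model, s.condition, s.context, s.n_time, rng) for s in series_set
        ]
        learned = learn_structure(sampled, cfg, prior)
        for edge in learned.learnable_edges():
            edge_counts[edge] = edge_counts.get(edge, 0) + 1
    rows = [
        (parent, child, count / B) for (parent, child), count in sorted(edge_counts.items())
    ]
    return EdgeFrequencyTable(
        frequencies=pd.DataFrame(rows, columns=["parent", "child", "frequency"]),
        B=B,
    )


def stable_edges(freqs: EdgeFrequencyTable, cutoff: float = 0.5) -> pd.DataFrame:
    """Edges with bootstrap frequency strictly above the cutoff.

    Sorted by descending frequency; self-loops are flagged so graph exports
    can drop them from display.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ConfigurationError("cutoff must lie in [0, 1]")
    df = freqs.frequencies
    keep = df["frequency"] > cutoff
    if cutoff >= 1.0:  # "present in every replicate" rather than the empty set
        keep = df["frequency"] >= 1.0
    out = df[keep].copy()
    out["self_loop"] = out["parent"] == out["child"]
    return out.sort_values(
        ["frequency", "parent", "child"], ascending=[False, True, True]
    ).reset_index(drop=True)


def write_edges_dot(edges: pd.DataFrame, path, include_self_loops: bool = False) -> None:
    """Minimal Graphviz DOT export with frequency edge labels."""
    with open(path, "w") as fh:
        fh.write("digraph dbn {\n")
        for _, row in edges.iterrows():
            if not include_self_loops and row.get("self_loop", row["parent"] == row["child"]):
                continue
            fh.write(
                f'  "{row["parent"]}" -> "{row["child"]}" [label="{row["frequency"]:.2f}"];\n'
            )
        fh.write("}\n")
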