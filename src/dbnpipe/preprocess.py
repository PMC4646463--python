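"""Replicate-level expression tables -> trinary differential-state series.

Pipeline, applied separately to the protein (RPPA) and transcript data:

1. transcript only: quantile normalization and a 1% detection-p filter;
2. technical-replicate correlation per molecule from a pooled one-way
   nested analysis of variance (blocks = biological replicates);
3. precision weights from a lowess mean-variance trend of the residual
   s.d. against the group mean;
4. per antibody/probe: weighted least squares on the factors "group"
   (condition x time) and "replicate" (biological replicate), empirical-
   Bayes moderated variances (optionally robust), stimulated-vs-control
   contrasts per time point, two-sided moderated-t p-values;
5. Benjamini-Hochberg FDR across all contrasts of the same data type; a
   contrast is called +1/-1 (sign of the log fold change) when its FDR is
   below the threshold, else 0;
6. antibody-level calls are summarized per molecule as the sign of their
   mean, and assembled into one trinary series per (context, condition).

The moderated-t machinery follows the published empirical-Bayes formulas
(inverse-chi-square prior on the residual variances, moments estimated on
the log scale); agreement with microarray-package implementations is
approximate, not bit-exact, which is immaterial downstream because only the
trinary calls are consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .dbn_core import CONTROL_CONDITION, DataError, TrinarySeries

logger = logging.getLogger("dbnpipe")

__all__ = [
    "PreprocessConfig",
    "estimate_tech_correlation",
    "precision_weights",
    "fit_differential_calls",
    "summarize_antibodies",
    "assemble_series",
    "discretize_table",
]

PROTEIN_CONTEXTS = ("cyt_protein", "nuc_protein")
TRANSCRIPT_CONTEXT = "transcript"

_GROUP_COLS = ["antibody", "context", "condition", "time"]
CALL_COLUMNS = ["molecule", "antibody", "context", "condition", "time", "log_fc", "p_value", "fdr", "call"]


@dataclass
class PreprocessConfig:
    fdr_threshold: float = 0.05
    detection_p_threshold: float = 0.01  # transcript probes only
    robust: bool = True  # robust empirical-Bayes variance shrinkage
    quantile_normalize: bool = True  # transcript context only

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "detection_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Technical-replicate correlation
# ---------------------------------------------------------------------------


def estimate_tech_correlation(table: pd.DataFrame) -> pd.Series:
    """Consensus within-biological-replicate correlation per molecule.

    One-way nested ANOVA pooled over all (antibody, context, condition,
    time) groups of a molecule, blocks = biological replicates, members =
    technical replicates: the intraclass correlation
    (MSB - MSW) / (MSB + (k-1) MSW) estimates the correlation between
    technical replicates sharing a biological replicate.  A molecule with a
    single technical replicate gets 0 with a logged warning.
    """
    out = {}
    block_cols = _GROUP_COLS + ["bio_rep"]
    for molecule, sub in table.groupby("molecule", sort=True):
        blocks = sub.groupby(block_cols)["value"].agg(n="count", mean="mean", ssq=lambda x: float((x**2).sum()))
        if blocks["n"].max() < 2:
            logger.warning("molecule %s has a single technical replicate; correlation set to 0", molecule)
            out[molecule] = 0.0
            continue
        ssw = float((blocks["ssq"] - blocks["n"] * blocks["mean"] ** 2).sum())
        dfw = int((blocks["n"] - 1).sum())
        grp = blocks.reset_index().groupby(_GROUP_COLS)
        ssb = dfb = 0.0
        for _, g in grp:
            if len(g) < 2:
                continue
            grand = float((g["n"] * g["mean"]).sum() / g["n"].sum())
            ssb += float((g["n"] * (g["mean"] - grand) ** 2).sum())
            dfb += len(g) - 1
        if dfb == 0 or dfw == 0:
            out[molecule] = 0.0
            continue
        msb, msw = ssb / dfb, ssw / dfw
        k = float(blocks["n"].mean())
        denom = msb + (k - 1.0) * msw
        icc = 0.0 if denom <= 0 else (msb - msw) / denom
        out[molecule] = float(np.clip(icc, -0.99, 0.99))
    return pd.Series(out, name="tech_correlation")


# ---------------------------------------------------------------------------
# Precision weights
# ---------------------------------------------------------------------------


def precision_weights(table: pd.DataFrame, min_groups: int = 10, frac: float = 0.6) -> np.ndarray:
    """Per-observation weights from a lowess mean-variance trend.

    The residual s.d. of every (antibody, context, condition, time) group is
    smoothed against the group mean; each observation's weight is the
    reciprocal predicted variance at its group mean.  With fewer than
    ``min_groups`` distinct groups the trend is unidentifiable and constant
    weights are returned with a warning.
    """
    grp = table.groupby(_GROUP_COLS)["value"]
    means = grp.transform("mean")
    stats_df = grp.agg(mean="mean", sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan)
    stats_df = stats_df.dropna()
    if len(stats_df) < min_groups:
        logger.warning("only %d groups: falling back to constant precision weights", len(stats_df))
        return np.ones(len(table))
    fitted = lowess(stats_df["sd"].to_numpy(), stats_df["mean"].to_numpy(), frac=frac, return_sorted=True)
    xs, ys = fitted[:, 0], np.maximum(fitted[:, 1], 1e-6)
    pred_sd = np.interp(means.to_numpy(), xs, ys)
    return 1.0 / np.maximum(pred_sd, 1e-6) ** 2


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray, robust: bool) -> tuple[float, float]:
    """Moment-match an inverse-chi-square prior (d0, s0^2) on log variances."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    df = np.asarray(df, dtype=float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if robust and e.size >= 3:
        med = np.median(e)
        mad = 1.4826 * np.median(np.abs(e - med))
        if mad > 0:
            e = np.clip(e, med - 2.5 * mad, med + 2.5 * mad)
    if e.size < 2:
        return 0.0, float(s2.mean())
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    target = evar - float(np.mean(special.polygamma(1, df / 2.0)))
    if target <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(target)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def _moderate(s2: np.ndarray, df: np.ndarray, robust: bool) -> tuple[np.ndarray, np.ndarray]:
    """Posterior variances and total degrees of freedom."""
    d0, s02 = _fit_variance_prior(s2, df, robust)
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s02), np.full(len(s2), 1e6)
    s2_post = (d0 * s02 + df * s2) / (d0 + df)
    return s2_post, df + d0


# ---------------------------------------------------------------------------
# Quantile normalization / detection filter (transcript)
# ---------------------------------------------------------------------------


def _quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across samples (columns = samples)."""
    table = table.copy()
    wide = table.pivot_table(
        index="antibody",
        columns=["condition", "time", "bio_rep", "tech_rep"],
        values="value",
    )
    if wide.shape[0] < 2 or wide.isna().any().any():
        return table
    ranks = wide.rank(axis=0, method="average")
    means = np.sort(wide.to_numpy(), axis=0).mean(axis=1)
    # map average ranks to the mean sorted profile by interpolation
    rank_grid = np.arange(1, wide.shape[0] + 1, dtype=float)
    normalized = wide.copy()
    for col in wide.columns:
        normalized[col] = np.interp(ranks[col].to_numpy(), rank_grid, means)
    long = (
        normalized.stack(["condition", "time", "bio_rep", "tech_rep"], future_stack=True)
        .rename("qn_value")
        .reset_index()
    )
    merged = table.merge(long, on=["antibody", "condition", "time", "bio_rep", "tech_rep"], how="left")
    table["value"] = merged["qn_value"].to_numpy()
    return table


def _detection_filter(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    med = table.groupby("antibody")["detection_p"].median()
    keep = med.index[med < threshold]
    dropped = sorted(set(med.index) - set(keep))
    if dropped:
        logger.info("detection filter removed %d probes", len(dropped))
    return table[table["antibody"].isin(keep)].copy()


# ---------------------------------------------------------------------------
# Differential calls
# ---------------------------------------------------------------------------


def _collapse_technical(table: pd.DataFrame, weights: np.ndarray, rho: pd.Series) -> pd.DataFrame:
    """Average technical replicates within biological replicate.

    The weight of the averaged value is k * w / (1 + (k-1) rho): the inverse
    variance of a mean of k equicorrelated observations, scaled by the
    precision weight of the trend.
    """
    t = table.copy()
    t["_w"] = weights
    t["_wv"] = t["_w"] * t["value"]
    agg = (
        t.groupby(["molecule"] + _GROUP_COLS + ["bio_rep"], sort=False)
        .agg(value=("_wv", "sum"), wsum=("_w", "sum"), k=("_w", "count"))
        .reset_index()
    )
    agg["value"] = agg["value"] / agg["wsum"]
    r = agg["molecule"].map(rho).fillna(0.0).to_numpy()
    k = agg["k"].to_numpy(dtype=float)
    agg["weight"] = (agg["wsum"] / k) * k / (1.0 + (k - 1.0) * r)
    return agg.drop(columns=["wsum", "k"])


def _fit_one_unit(sub: pd.DataFrame) -> pd.DataFrame | None:
    """WLS fit of value ~ group + replicate for one (antibody, context).

    Returns per-contrast rows with the log fold change, the unit contrast
    variance and the residual variance/df shared by the unit.
    """
    groups = sub[["condition", "time"]].drop_duplicates()
    conditions = sorted(sub["condition"].unique())
    if CONTROL_CONDITION not in conditions:
        raise DataError(
            f"missing control group for antibody {sub['antibody'].iat[0]!r} "
            f"in context {sub['context'].iat[0]!r}"
        )
    group_key = sub["condition"].astype(str) + "@" + sub["time"].astype(str)
    group_levels = sorted(group_key.unique())
    gidx = pd.Categorical(group_key, categories=group_levels).codes
    reps = sorted(sub["bio_rep"].unique())
    ridx = pd.Categorical(sub["bio_rep"], categories=reps).codes
    n, G, R = len(sub), len(group_levels), len(reps)
    X = np.zeros((n, G + max(R - 1, 0)))
    X[np.arange(n), gidx] = 1.0
    for j in range(1, R):
        X[ridx == j, G + j - 1] = 1.0
    w = sub["weight"].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    sw = np.sqrt(w)
    A = X * sw[:, None]
    b = y * sw
    beta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    dof = n - rank
    if dof <= 0:
        raise DataError(
            f"zero residual degrees of freedom for antibody {sub['antibody'].iat[0]!r}"
        )
    rss = float(((b - A @ beta) ** 2).sum())
    s2 = rss / dof
    xtwx_inv = np.linalg.pinv(A.T @ A)
    level_pos = {lev: i for i, lev in enumerate(group_levels)}
    rows = []
    for _, g in groups.iterrows():
        cond, time = g["condition"], g["time"]
        if cond == CONTROL_CONDITION:
            continue
        ctrl_key = f"{CONTROL_CONDITION}@{time}"
        if ctrl_key not in level_pos:
            raise DataError(f"missing control group for time point {time} ({cond!r})")
        c = np.zeros(X.shape[1])
        c[level_pos[f"{cond}@{time}"]] = 1.0
        c[level_pos[ctrl_key]] = -1.0
        lfc = float(c @ beta)
        var_unit = float(c @ xtwx_inv @ c)
        rows.append(
            (
                sub["molecule"].iat[0],
                sub["antibody"].iat[0],
                sub["context"].iat[0],
                cond,
                time,
                lfc,
                var_unit,
                s2,
                dof,
            )
        )
    if not rows:
        return None
    return pd.DataFrame(
        rows,
        columns=["molecule", "antibody", "context", "condition", "time", "log_fc", "var_unit", "s2", "dof"],
    )


def _calls_for_datatype(table: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    rho = estimate_tech_correlation(table)
    weights = precision_weights(table)
    bio = _collapse_technical(table, weights, rho)
    units = []
    for _, sub in bio.groupby(["antibody", "context"], sort=True):
        fit = _fit_one_unit(sub)
        if fit is not None:
            units.append(fit)
    if not units:
        return pd.DataFrame(columns=CALL_COLUMNS)
    res = pd.concat(units, ignore_index=True)
    # one pooled variance per fitted unit enters the EB moment fit once
    unit_var = res.drop_duplicates(["antibody", "context"])[["antibody", "context", "s2", "dof"]]
    s2_post, dof_total = _moderate(
        unit_var["s2"].to_numpy(), unit_var["dof"].to_numpy(), cfg.robust
    )
    unit_var = unit_var.assign(s2_post=s2_post, dof_total=dof_total).drop(columns=["s2", "dof"])
    res = res.merge(unit_var, on=["antibody", "context"], how="left")
    tstat = res["log_fc"] / np.sqrt(res["var_unit"] * res["s2_post"])
    res["p_value"] = 2.0 * stats.t.sf(np.abs(tstat), res["dof_total"])
    res["fdr"] = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    res["call"] = np.where(
        res["fdr"] < cfg.fdr_threshold, np.sign(res["log_fc"]).astype(int), 0
    ).astype(np.int8)
    return res[CALL_COLUMNS]


def fit_differential_calls(table: pd.DataFrame, cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """Differential trinary calls versus control for every antibody/probe.

    The protein and transcript data are analyzed separately (each gets its
    own variance prior and its own BH correction); transcript data are
    quantile normalized and detection-filtered first.
    """
    cfg = cfg or PreprocessConfig()
    pieces = []
    protein = table[table["context"].isin(PROTEIN_CONTEXTS)]
    if len(protein):
        pieces.append(_calls_for_datatype(protein, cfg))
    transcript = table[table["context"] == TRANSCRIPT_CONTEXT]
    if len(transcript):
        if "detection_p" in transcript.columns and transcript["detection_p"].notna().any():
            transcript = _detection_filter(transcript, cfg.detection_p_threshold)
        if cfg.quantile_normalize:
            transcript = _quantile_normalize(transcript)
        pieces.append(_calls_for_datatype(transcript, cfg))
    if not pieces:
        raise DataError("expression table contains no recognized context")
    return pd.concat(pieces, ignore_index=True)


def summarize_antibodies(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-molecule summary: the sign of the mean of the antibody-level calls."""
    if not len(calls):
        raise DataError("no differential calls to summarize")
    grp = (
        calls.groupby(["molecule", "context", "condition", "time"], sort=True)["call"]
        .mean()
        .reset_index()
    )
    grp["call"] = np.sign(grp["call"]).astype(np.int8)
    return grp


def assemble_series(summary: pd.DataFrame) -> list[TrinarySeries]:
    """One trinary series per (context, condition) from molecule-level calls.

    Stimulation-node values are implied by the condition label; a missing
    time point raises an error naming the gap.
    """
    series = []
    all_times = sorted(summary["time"].unique())
    if all(float(t).is_integer() for t in all_times):
        all_times = list(range(int(all_times[0]), int(all_times[-1]) + 1))
    for (context, condition), sub in summary.groupby(["context", "condition"], sort=True):
        wide = sub.pivot_table(index="molecule", columns="time", values="call", aggfunc="first")
        gaps = [t for t in all_times if t not in wide.columns or wide[t].isna().any()]
        if gaps:
            raise DataError(
                f"incomplete time grid for ({context}, {condition}): missing {gaps}"
            )
        s = TrinarySeries(
            states=wide[all_times].astype(np.int8),
            condition=condition,
            context=context,
            name=f"{context}:{condition}",
        )
        series.append(s)
    return series


def discretize_table(table: pd.DataFrame, cfg: PreprocessConfig | None = None):
    """Full preprocessing chain: calls -> molecule summary -> trinary series.

    Returns (calls, summary, series); control conditions never form a series
    (they are the reference).
    """
    calls = fit_differential_calls(table, cfg)
    summary = summarize_antibodies(calls)
    return calls, summary, assemble_series(summary)
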