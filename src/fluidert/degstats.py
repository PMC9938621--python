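"""Per-gene differential expression across the three receptivity stages.

Each gene's log2 expression is decomposed as baseline + cycle-protocol
(treatment) effect + receptivity-stage effect + residual; the stage effect
is tested with the F-ratio of the stage mean square to the residual mean
square, p-values are adjusted by Benjamini-Hochberg FDR (q-values), and all
three stage pairs are compared post hoc with Tukey's honestly-significant-
difference test (Tukey-Kramer for unequal group sizes).

The ANOVA is fitted as a fixed-effects main-effects model; for the balanced
stage-timed design without interaction this F statistic coincides with the
variance-components formulation of the stage test.  Sums of squares are
computed for all genes at once via shared projection matrices, since the
design is identical across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exprio import ExpressionDataset, STAGES

PAIRS = (("PR", "RE"), ("RE", "PO"), ("PR", "PO"))
_ZERO_TOL = 1e-12


class DesignError(ValueError):
    """The sample layout cannot support the requested test."""


def _stage_groups(dataset: ExpressionDataset) -> dict[str, np.ndarray]:
    stages = dataset.stages()
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise DesignError(f"unknown stage labels: {unknown}")
    groups = {s: np.flatnonzero((stages == s).to_numpy()) for s in STAGES}
    for s, idx in groups.items():
        if len(idx) < 2:
            raise DesignError(f"stage {s} has {len(idx)} samples; need >= 2")
    return groups


def _projection(X: np.ndarray) -> np.ndarray:
    # hat matrix X (X'X)^+ X'; pinv tolerates rank deficiency
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def anova_per_gene(dataset: ExpressionDataset,
                   include_treatment: bool = False) -> pd.DataFrame:
    """Stage-effect ANOVA for every gene; returns one row per gene.

    Columns: per-stage means, sums of squares with degrees of freedom, mean
    squares, F, p_value, q_value, and a ``degenerate`` flag (``zero_variance``
    for constant genes, which get p = 1; ``zero_residual`` for perfectly
    separated genes, which get p = 0).

    The treatment (cycle protocol) term is fitted only when requested and the
    protocol column actually varies; otherwise the model reduces to a one-way
    layout over PR/RE/PO.
    """
    if dataset.scale != "log2":
        raise DesignError(f"ANOVA expects log2 scale, got {dataset.scale}")
    groups = _stage_groups(dataset)
    Y = dataset.values.to_numpy(dtype=float)
    n = Y.shape[1]

    stage_d = pd.get_dummies(dataset.stages()).reindex(columns=list(STAGES)).to_numpy(float)
    protocols = dataset.sample_meta["protocol"]
    fit_treatment = include_treatment and protocols.nunique() > 1
    if include_treatment and protocols.isna().any():
        raise DesignError("include_treatment requires a protocol label on every sample")

    intercept = np.ones((n, 1))
    X_stage = stage_d[:, 1:]  # drop one level
    blocks = [intercept, X_stage]
    b_levels = 1
    if fit_treatment:
        proto_d = pd.get_dummies(protocols).to_numpy(float)
        blocks.append(proto_d[:, 1:])
        b_levels = proto_d.shape[1]
    X_full = np.hstack(blocks)
    P_full = _projection(X_full)
    X_nostage = np.hstack([b for i, b in enumerate(blocks) if i != 1])
    P_nostage = _projection(X_nostage)
    P_mean = _projection(intercept)

    def rss(P):
        R = Y - Y @ P
        return np.einsum("ij,ij->i", R, R)

    ss_error = rss(P_full)
    ss_total = rss(P_mean)
    ss_stage = rss(P_nostage) - ss_error
    if fit_treatment:
        P_notreat = _projection(np.hstack([intercept, X_stage]))
        ss_treatment = rss(P_notreat) - ss_error
    else:
        ss_treatment = np.zeros_like(ss_error)

    k = len(STAGES)
    df_stage = k - 1
    df_error = n - 1 - df_stage - (b_levels - 1)
    if df_error <= 0:
        raise DesignError("no residual degrees of freedom")

    scale = np.maximum(ss_total, 1.0)
    zero_var = ss_total <= _ZERO_TOL * scale
    zero_resid = (~zero_var) & (ss_error <= _ZERO_TOL * scale)

    ms_stage = ss_stage / df_stage
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_error = ss_error / df_error
        F = ms_stage / ms_error
    p = stats.f.sf(F, df_stage, df_error)
    F = np.where(zero_resid, np.inf, F)
    p = np.where(zero_resid, 0.0, p)
    F = np.where(zero_var, 0.0, F)
    p = np.where(zero_var, 1.0, p)

    out = pd.DataFrame(index=dataset.values.index)
    for s in STAGES:
        out[f"mean_{s}"] = Y[:, groups[s]].mean(axis=1)
    out["ss_stage"] = np.maximum(ss_stage, 0.0)
    out["ss_treatment"] = np.maximum(ss_treatment, 0.0)
    out["ss_error"] = np.maximum(ss_error, 0.0)
    out["ss_total"] = ss_total
    out["df_stage"] = df_stage
    out["df_error"] = df_error
    out["ms_stage"] = out["ss_stage"] / df_stage
    out["ms_error"] = out["ss_error"] / df_error
    out["F"] = F
    out["p_value"] = p
    out["q_value"] = bh_fdr(p)
    out["degenerate"] = np.where(zero_var, "zero_variance",
                                 np.where(zero_resid, "zero_residual", ""))
    for a, b in PAIRS:
        out[f"lfc_{a}_{b}"] = out[f"mean_{b}"] - out[f"mean_{a}"]
    return out


def bh_fdr(p_values, propagate_nan: bool = False) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    nan = np.isnan(p)
    if nan.any() and not propagate_nan:
        raise ValueError("NaN p-values; pass propagate_nan=True to keep them")
    if ((p[~nan] < 0) | (p[~nan] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if (~nan).sum():
        q[~nan] = multipletests(p[~nan], method="fdr_bh")[1]
    return q


def pairwise_log2fc(dataset: ExpressionDataset, stage_a: str, stage_b: str) -> pd.Series:
    """Per-gene log2 fold change mean(stage_b) - mean(stage_a)."""
    if dataset.scale != "log2":
        raise DesignError("fold changes are defined on the log2 scale")
    stages = dataset.stages()
    for s in (stage_a, stage_b):
        if not (stages == s).any():
            raise DesignError(f"stage {s} absent from dataset")
    mean_a = dataset.values.loc[:, (stages == stage_a).to_numpy()].mean(axis=1)
    mean_b = dataset.values.loc[:, (stages == stage_b).to_numpy()].mean(axis=1)
    return (mean_b - mean_a).rename(f"lfc_{stage_a}_{stage_b}")


def volcano_classify(p_values, log2fc, p_cut: float = 0.05,
                     fc_cut: float = 2.0) -> np.ndarray:
    """Volcano classes up/down/ns at p < p_cut and |log2FC| >= log2(fc_cut).

    The fold-change boundary is inclusive, the p boundary exclusive.
    """
    if fc_cut <= 1:
        raise ValueError("fc_cut must be > 1")
    p = np.asarray(p_values, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    thr = np.log2(fc_cut)
    cls = np.where((p < p_cut) & (lfc >= thr), "up",
                   np.where((p < p_cut) & (lfc <= -thr), "down", "ns"))
    return cls


# -- Tukey HSD ----------------------------------------------------------------

_SR_CACHE: dict[tuple[int, int], object] = {}


def _sr_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Studentized-range survival function, interpolated for large batches.

    The design (hence df) is shared across genes, so a monotone interpolant
    of log-sf on a dense grid replaces per-gene quadrature; grid accuracy is
    far below the Monte-Carlo tolerance used to validate these p-values.
    """
    q = np.asarray(q, dtype=float)
    if q.size <= 64:
        return stats.studentized_range.sf(q, k, df)
    key = (k, df)
    if key not in _SR_CACHE:
        from scipy.interpolate import PchipInterpolator
        grid = np.concatenate([np.linspace(0.0, 10.0, 401), np.linspace(10.05, 60.0, 400)])
        sf = stats.studentized_range.sf(grid, k, df)
        sf = np.clip(sf, 1e-300, 1.0)
        _SR_CACHE[key] = PchipInterpolator(grid, np.log(sf), extrapolate=True)
    out = np.exp(_SR_CACHE[key](np.clip(q, 0.0, 60.0)))
    out[q > 60.0] = 0.0
    return np.clip(out, 0.0, 1.0)


def tukey_hsd_per_gene(dataset: ExpressionDataset,
                       anova: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tukey HSD p-values for all three stage pairs, one row per gene.

    The statistic for pair (i, j) is |mean_i - mean_j| /
    sqrt((MS_error / 2) * (1/n_i + 1/n_j)) (Tukey-Kramer), referred to the
    studentized-range distribution with k = 3 groups and the one-way error
    df.  Degenerate genes get p = 1 on every pair.
    """
    groups = _stage_groups(dataset)
    if anova is None or "ms_error" not in anova:
        anova = anova_per_gene(dataset)
    anova = anova.loc[dataset.values.index]
    Y = dataset.values.to_numpy(dtype=float)
    n_total = Y.shape[1]
    df_error = n_total - len(STAGES)
    # one-way residual mean square, recomputed in case `anova` fitted treatment
    ss_err = np.zeros(Y.shape[0])
    means = {}
    for s, idx in groups.items():
        sub = Y[:, idx]
        means[s] = sub.mean(axis=1)
        ss_err += ((sub - means[s][:, None]) ** 2).sum(axis=1)
    mse = ss_err / df_error

    zero_var = (anova["degenerate"] == "zero_variance").to_numpy()
    out = pd.DataFrame(index=dataset.values.index)
    for a, b in PAIRS:
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            qstat = np.abs(means[a] - means[b]) / se
        qstat = np.where(np.isnan(qstat), 0.0, qstat)
        p = np.where(np.isinf(qstat), 0.0, _sr_sf(np.where(np.isinf(qstat), 0, qstat),
                                                  len(STAGES), df_error))
        p = np.where(zero_var, 1.0, p)
        out[f"tukey_p_{a}_{b}"] = p
    out["degenerate"] = anova["degenerate"]
    return out


def compute_gene_stats(dataset: ExpressionDataset,
                       include_treatment: bool = False,
                       p_cut: float = 0.05, fc_cut: float = 2.0) -> pd.DataFrame:
    """Full per-gene statistics table: ANOVA + Tukey + volcano classes."""
    stats_df = anova_per_gene(dataset, include_treatment=include_treatment)
    tukey = tukey_hsd_per_gene(dataset, stats_df)
    stats_df = stats_df.join(tukey.drop(columns="degenerate"))
    for a, b in PAIRS:
        stats_df[f"volcano_{a}_{b}"] = volcano_classify(
            stats_df["p_value"], stats_df[f"lfc_{a}_{b}"], p_cut, fc_cut)
    return stats_df
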