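"""Marker-panel assembly: Tukey all-pairwise filter, random-forest dual
importances, and hub-gene augmentation.

Candidate genes must separate every pair of receptivity stages (all three
Tukey HSD p-values below alpha).  A bagged ensemble of decision trees is
then fitted on the candidates versus the three stage labels and each gene is
scored by two classic forest importances: mean decrease accuracy (the drop
in out-of-bag accuracy when the gene's values are permuted, averaged over
trees and permutation repeats) and mean decrease Gini (total impurity
decrease attributed to splits on the gene).  The panel takes the top genes
by the dual-importance rule and appends the non-grey module hub genes.

The bagging loop is explicit (rather than a stock forest object) because
mean decrease accuracy needs per-tree out-of-bag bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .exprio import ExpressionDataset

DEFAULT_PANEL_SIZE = 87
DEFAULT_ALPHA = 0.05


class SelectionError(ValueError):
    """Marker selection cannot proceed with the given inputs."""


@dataclass
class RFConfig:
    """Forest settings shared by selection and classification."""

    n_trees: int = 500
    max_features: str | float = "sqrt"
    n_permutations: int = 5
    seed: int = 0


@dataclass
class MarkerPanel:
    """Ranked marker genes with dual importances and provenance."""

    table: pd.DataFrame  # columns: gene, mda, gini, source, rank
    panel_size: int
    alpha: float
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def tukey_filter(gene_stats: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Genes whose three pairwise Tukey p-values are all below alpha.

    Degenerate (zero-variance) genes are never candidates.
    """
    cols = [c for c in gene_stats.columns if c.startswith("tukey_p_")]
    if len(cols) != 3:
        raise SelectionError("gene_stats lacks the three Tukey p-value columns; "
                             "run tukey_hsd_per_gene first")
    if not (0 < alpha <= 1):
        raise SelectionError("alpha must lie in (0, 1]")
    ok = (gene_stats[cols] < alpha).all(axis=1)
    if "degenerate" in gene_stats:
        ok &= gene_stats["degenerate"] == ""
    return list(gene_stats.index[ok])


def _bootstrap_oob(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, n, size=n)
    oob = np.ones(n, dtype=bool)
    oob[idx] = False
    return idx, np.flatnonzero(oob)


def rf_dual_importance_rank(dataset: ExpressionDataset, candidates,
                            config: RFConfig | None = None) -> pd.DataFrame:
    """Mean-decrease-accuracy and mean-decrease-Gini scores per candidate.

    Fits ``n_trees`` bootstrap decision trees (features-per-split
    ``max_features``) on candidates vs stage labels.  MDA permutes one
    feature at a time on each tree's out-of-bag samples
    (``n_permutations`` repeats) and averages the accuracy drop; MDG
    averages the unnormalized impurity decrease across trees.  Deterministic
    given the seed.
    """
    config = config or RFConfig()
    candidates = list(candidates)
    if not candidates:
        raise SelectionError("no candidate genes to rank")
    sub = dataset.subset_genes(candidates)
    if len(sub.gene_ids) != len(candidates):
        missing = sorted(set(candidates) - set(sub.gene_ids))
        raise SelectionError(f"candidate genes absent from matrix: {missing[:5]}")
    y = sub.stages().to_numpy()
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise SelectionError("need >= 2 stage classes to rank markers")
    counts = np.bincount(y_enc)
    if (counts < 2).any():
        raise SelectionError("every stage class needs >= 2 samples")

    X = np.ascontiguousarray(sub.values.to_numpy(dtype=np.float32).T)  # samples x genes
    n, p = X.shape
    rng = np.random.default_rng(config.seed)
    mda = np.zeros(p)
    gini = np.zeros(p)
    n_oob_trees = 0
    for _ in range(config.n_trees):
        boot, oob = _bootstrap_oob(rng, n)
        tree = DecisionTreeClassifier(max_features=config.max_features,
                                      random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[boot], y_enc[boot])
        gini += tree.tree_.compute_feature_importances(normalize=False)
        if len(oob) == 0:
            continue
        n_oob_trees += 1
        X_oob = np.ascontiguousarray(X[oob], dtype=np.float32)
        y_oob = y_enc[oob]
        cls = tree.classes_.astype(int)

        def _predict(mat):
            votes = tree.tree_.predict(mat)
            if votes.ndim == 3:
                votes = votes[:, 0, :]
            return cls[votes.argmax(axis=1)]

        base = (_predict(X_oob) == y_oob).mean()
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            drop = 0.0
            col = X_oob[:, f].copy()
            for _ in range(config.n_permutations):
                X_oob[:, f] = col[rng.permutation(len(col))]
                acc = (_predict(X_oob) == y_oob).mean()
                drop += base - acc
            X_oob[:, f] = col
            mda[f] += drop / config.n_permutations
    if n_oob_trees:
        mda /= n_oob_trees
    gini /= config.n_trees

    out = pd.DataFrame({"gene": sub.gene_ids, "mda": mda, "gini": gini})
    out = out.sort_values(["mda", "gini", "gene"],
                          ascending=[False, False, True], kind="mergesort")
    return out.reset_index(drop=True)


def assemble_panel(ranked: pd.DataFrame, hubs,
                   panel_size: int = DEFAULT_PANEL_SIZE,
                   alpha: float = DEFAULT_ALPHA,
                   seed: int = 0) -> MarkerPanel:
    """Top-ranked genes plus module hubs, deduplicated.

    Selection rule: rank by mean decrease accuracy, but require membership in
    the top ``2 * panel_size`` genes by Gini; if that leaves fewer than
    ``panel_size`` genes, fall back to the pure accuracy ranking.  Hubs
    already selected keep their ``tukey_rf`` provenance and are not
    double-counted.
    """
    if panel_size < 1:
        raise SelectionError("panel_size must be >= 1")
    hubs = list(dict.fromkeys(hubs))
    notes = []
    if len(ranked) < panel_size:
        notes.append(f"only {len(ranked)} candidates for panel_size {panel_size}")
        chosen = list(ranked["gene"])
    else:
        gini_order = ranked.sort_values(["gini", "mda", "gene"],
                                        ascending=[False, False, True], kind="mergesort")
        gini_top = set(gini_order["gene"].head(2 * panel_size))
        eligible = ranked[ranked["gene"].isin(gini_top)]
        if len(eligible) >= panel_size:
            chosen = list(eligible["gene"].head(panel_size))
        else:
            notes.append("dual-importance intersection too small; "
                         "fell back to accuracy ranking")
            chosen = list(ranked["gene"].head(panel_size))
    scores = ranked.set_index("gene")
    rows = []
    for g in chosen:
        rows.append({"gene": g, "mda": scores.at[g, "mda"],
                     "gini": scores.at[g, "gini"], "source": "tukey_rf"})
    selected = {r["gene"] for r in rows}
    for h in hubs:
        if h in selected:
            continue
        mda = scores.at[h, "mda"] if h in scores.index else np.nan
        gini = scores.at[h, "gini"] if h in scores.index else np.nan
        rows.append({"gene": h, "mda": mda, "gini": gini, "source": "hub"})
    table = pd.DataFrame(rows)
    table["rank"] = np.arange(1, len(table) + 1)
    for note in notes:
        warnings.warn(note)
    return MarkerPanel(table, panel_size, alpha, seed, notes)


def select_markers(dataset: ExpressionDataset, gene_stats: pd.DataFrame,
                   hubs, panel_size: int = DEFAULT_PANEL_SIZE,
                   alpha: float = DEFAULT_ALPHA,
                   rf_config: RFConfig | None = None) -> MarkerPanel:
    """End-to-end marker selection: Tukey filter -> RF ranking -> panel."""
    rf_config = rf_config or RFConfig()
    candidates = tukey_filter(gene_stats, alpha)
    if not candidates:
        raise SelectionError("no gene passes the all-pairwise Tukey filter")
    ranked = rf_dual_importance_rank(dataset, candidates, rf_config)
    return assemble_panel(ranked, hubs, panel_size, alpha, rf_config.seed)
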