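"""Clinical association of WOI calls with pregnancy outcomes.

The validation readout is a 2x2 contingency table — rows: normal WOI
(receptive call) versus displaced WOI (pre- or post-receptive call);
columns: intrauterine pregnancy success versus failure — tested with
Fisher's exact test (two-sided, sum-of-smaller-probabilities convention).
Samples whose library failed sequencing QC or whose call fell below the
probability threshold are excluded from the table but kept in the overall
cohort denominators, matching how the study reports its rates.

Also provides a generic hypergeometric over-representation test for gene
sets (fold enrichment, upper-tail p, BH-FDR across sets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .degstats import bh_fdr

NORMAL_CALLS = ("RE",)
DISPLACED_CALLS = ("PR", "PO")


class TableError(ValueError):
    """Invalid contingency-table input."""


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio for a 2x2 table.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's.  The odds ratio is (a*d)/(b*c); with a zero in b or c it is
    reported as ``inf``, and as ``nan`` when the ratio is 0/0.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise TableError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise TableError("cells must be non-negative integers")
    arr = arr.astype(int)
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).all() or (arr.sum(axis=1) == 0).all():
        raise TableError("table needs at least one positive margin")
    res = stats.fisher_exact(arr, alternative="two-sided")
    a, b = arr[0]
    c, d = arr[1]
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(res.pvalue), float(odds)


@dataclass
class OutcomeTable:
    """WOI-by-outcome 2x2 summary with exact inference."""

    counts: pd.DataFrame  # rows normal/displaced, cols success/failure
    fisher_p: float
    odds_ratio: float
    excluded: dict[str, list[str]] = field(default_factory=dict)
    n_enrolled: int = 0

    @property
    def normal_rate(self) -> float:
        row = self.counts.loc["normal"]
        return float(row["success"] / row.sum()) if row.sum() else np.nan

    @property
    def displaced_rate(self) -> float:
        row = self.counts.loc["displaced"]
        return float(row["success"] / row.sum()) if row.sum() else np.nan

    @property
    def overall_rate(self) -> float:
        """Successes over ALL enrolled samples, failures included."""
        if not self.n_enrolled:
            return np.nan
        return float(self.counts["success"].sum() / self.n_enrolled)

    def to_json(self, path) -> None:
        payload = {
            "counts": {r: {c: int(v) for c, v in row.items()}
                       for r, row in self.counts.iterrows()},
            "fisher_p": self.fisher_p,
            "odds_ratio": None if np.isnan(self.odds_ratio) else self.odds_ratio,
            "normal_rate": self.normal_rate,
            "displaced_rate": self.displaced_rate,
            "overall_rate": self.overall_rate,
            "n_enrolled": self.n_enrolled,
            "excluded": self.excluded,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def outcome_association(predictions: pd.DataFrame, outcomes: pd.Series) -> OutcomeTable:
    """Assemble the WOI-by-pregnancy table from a prediction report.

    ``predictions`` is the per-sample report with ``call`` and ``woi``
    columns; ``outcomes`` maps sample id to ``pregnant`` / ``not_pregnant``.
    Detection failures and indeterminate (no-call) samples are excluded from
    the table but counted in ``n_enrolled`` for the overall rate.
    """
    excluded = {"detection_failed": [], "indeterminate": []}
    rows = {"normal": {"success": 0, "failure": 0},
            "displaced": {"success": 0, "failure": 0}}
    for sample, rec in predictions.iterrows():
        woi = rec["woi"]
        if woi in excluded:
            excluded[woi].append(sample)
            continue
        if sample not in outcomes.index or outcomes[sample] in (None, "unknown", np.nan):
            raise TableError(f"missing outcome for analyzable sample {sample!r}")
        group = "normal" if rec["call"] in NORMAL_CALLS else "displaced"
        col = "success" if outcomes[sample] == "pregnant" else "failure"
        rows[group][col] += 1
    counts = pd.DataFrame(rows).T[["success", "failure"]]
    if counts.to_numpy().sum() == 0:
        raise TableError("no analyzable samples: every prediction was excluded")
    p, odds = fisher_exact_2x2(counts.to_numpy())
    return OutcomeTable(counts, p, odds, excluded, n_enrolled=len(predictions))


def hypergeometric_ora(query_set, annotation_sets: dict, background) -> pd.DataFrame:
    """Over-representation of a gene list in annotation sets.

    For each set: overlap k, fold enrichment (k/n)/(K/N) and upper-tail
    hypergeometric p = P(X >= k) drawing n from N with K annotated; BH-FDR
    across sets.  Empty overlap gives fold 0 and p 1.
    """
    background = set(background)
    if not background:
        raise TableError("empty background")
    query = set(query_set)
    if not query <= background:
        raise TableError("query set must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for name, members in annotation_sets.items():
        members = set(members) & background
        K = len(members)
        k = len(query & members)
        fold = (k / n) / (K / N) if n and K else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "fold_enrichment": fold, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out
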