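"""Gene-level score aggregation and ROC/AUC evaluation.

Intron-level essentiality scores are aggregated to genes by the majority
classifier (the mean of a gene's per-intron scores) and the double
classifier (the pooled mean over intron scores from both the first-window
and last-window models).  ROC curves sweep all distinct score thresholds
with tied scores grouped, which makes the trapezoidal AUC equal to the
Mann-Whitney U statistic divided by n1*n2 with ties credited 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RocResult",
    "roc_auc",
    "majority_gene_score",
    "double_gene_score",
    "make_score_table",
    "gene_score_table",
    "evaluate_suite",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoidal AUC for binary integer labels (1 = positive).

    Raises ``ValueError`` when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # group tied scores: cut where the sorted score changes
    distinct = np.flatnonzero(np.diff(s_sorted)) + 1
    bounds = np.concatenate([distinct, [len(s_sorted)]])
    tp = np.cumsum(y_sorted)[bounds - 1]
    fp = bounds - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[bounds - 1]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def majority_gene_score(intron_scores) -> float:
    """Gene essentiality score: the mean of its introns' scores."""
    intron_scores = np.asarray(intron_scores, dtype=float)
    if intron_scores.size == 0:
        raise ValueError("gene has no intron scores")
    return float(intron_scores.mean())


def double_gene_score(first_scores, last_scores) -> float:
    """Pooled mean over intron scores from both window models.

    Since both models score the same introns this equals the average of
    the two per-model gene means.
    """
    first_scores = np.asarray(first_scores, dtype=float)
    last_scores = np.asarray(last_scores, dtype=float)
    if first_scores.size == 0 or last_scores.size == 0:
        raise ValueError("gene has no intron scores")
    return float(np.concatenate([first_scores, last_scores]).mean())


def make_score_table(
    gene_ids, ordinals, scores, model_kind: str
) -> pd.DataFrame:
    """Assemble per-intron scores into the canonical long-format table."""
    if model_kind not in ("first", "last"):
        raise ValueError("model_kind must be 'first' or 'last'")
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "ordinal": list(ordinals),
            "model_kind": model_kind,
            "score": np.asarray(scores, dtype=float),
        }
    )


def gene_score_table(score_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene majority scores from each model plus the double score."""
    wide = score_table.pivot_table(
        index="gene_id", columns="model_kind", values="score", aggfunc="mean"
    )
    out = pd.DataFrame(index=wide.index)
    if "first" in wide:
        out["majority_first"] = wide["first"]
    if "last" in wide:
        out["majority_last"] = wide["last"]
    if "first" in wide and "last" in wide:
        # pooled mean == average of the two per-model means (same introns)
        out["double"] = (wide["first"] + wide["last"]) / 2.0
    return out.reset_index()


def evaluate_suite(score_table: pd.DataFrame, labels: dict[str, int]) -> pd.DataFrame:
    """AUC report across intron-level, gene-level, and first-intron views.

    ``labels`` maps gene_id to 1 (essential) / 0 (nonessential); genes
    absent from the map are ignored.  Rows: intron-level AUC for each
    window model, majority-classifier AUC for each model, the double
    classifier, and the first-intron dual average (the mean of both
    models' scores on the intron with ordinal 1).
    """
    t = score_table[score_table["gene_id"].isin(labels)].copy()
    t["y"] = t["gene_id"].map(labels).astype(int)
    rows = []

    def _add(name: str, scores, ys) -> None:
        scores = np.asarray(scores, dtype=float)
        ys = np.asarray(ys, dtype=int)
        rows.append(
            {"metric": name, "auc": roc_auc(scores, ys).auc, "n": len(scores)}
        )

    for kind in ("first", "last"):
        sub = t[t["model_kind"] == kind]
        if len(sub):
            _add(f"intron_{kind}", sub["score"], sub["y"])
    gene_scores = gene_score_table(t)
    ymap = pd.Series(labels)
    gy = gene_scores["gene_id"].map(ymap).astype(int)
    for col, name in [
        ("majority_first", "majority_first"),
        ("majority_last", "majority_last"),
        ("double", "double"),
    ]:
        if col in gene_scores:
            _add(name, gene_scores[col], gy)
    first_introns = t[t["ordinal"] == 1]
    if len(first_introns):
        for kind in ("first", "last"):
            sub = first_introns[first_introns["model_kind"] == kind]
            if len(sub):
                _add(f"first_intron_{kind}", sub["score"], sub["y"])
        dual = first_introns.pivot_table(
            index="gene_id", columns="model_kind", values="score"
        )
        if {"first", "last"} <= set(dual.columns):
            dual_score = (dual["first"] + dual["last"]) / 2.0
            dual_y = dual.index.to_series().map(ymap).astype(int)
            _add("first_intron_dual", dual_score.values, dual_y.values)
    return pd.DataFrame(rows)
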