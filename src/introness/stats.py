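"""Group-comparison statistics and figure-style summary tables.

Summaries follow the presentation of notched box plots of intron
properties split six ways (essential / conditional / nonessential x
first / later intron), with Gaussian-asymptotic notches
(median +- 1.57 * IQR / sqrt(n)) and two-sided Mann-Whitney rank tests
between groups.  For small samples (n_a + n_b <= 12) the rank test
p-value is computed by exact enumeration of group assignments; otherwise
the tie-corrected normal approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["rank_test", "notch_interval", "GroupSummary", "build_report"]

EXACT_LIMIT = 12  # total sample size at or below which enumeration is exact


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a (ties counted 1/2), by midranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def rank_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank test; returns (U of sample_a, p).

    The two-sided p-value is the probability, under random relabeling,
    of a U at least as far from its null mean n_a*n_b/2 as observed.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if n_a + n_b <= EXACT_LIMIT:
        # exact enumeration of all C(n_a+n_b, n_a) group assignments
        pooled = np.concatenate([a, b])
        n = n_a + n_b
        mid = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mid)
        hits = 0
        for idx_a in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mid) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / comb(n, n_a)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def notch_interval(sample) -> tuple[float, float]:
    """Gaussian-asymptotic notch around the median: m +- 1.57*IQR/sqrt(n)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    q1, q3 = np.percentile(x, [25, 75])
    half = 1.57 * (q3 - q1) / np.sqrt(len(x))
    return med - half, med + half


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float


def _summarize(group: str, values: np.ndarray) -> GroupSummary:
    q1, q3 = np.percentile(values, [25, 75])
    lo, hi = notch_interval(values)
    return GroupSummary(
        group=group, n=len(values), mean=float(values.mean()),
        median=float(np.median(values)), q1=float(q1), q3=float(q3),
        notch_low=lo, notch_high=hi,
    )


_INTRON_METRICS = ["length", "gc_density", "gc_excl"]
_INTRON_FLAGS = ["unusual_5p", "unusual_3p", "cpg_present"]
_GENE_METRICS = ["n_introns", "total_intronic_bp", "avg_intron_size"]
_CATEGORIES = ["essential", "conditional", "nonessential"]


def build_report(
    intron_df: pd.DataFrame,
    gene_df: pd.DataFrame,
    bh_correct: bool = False,
) -> dict[str, pd.DataFrame]:
    """Six-group summaries and pairwise rank tests in the style of the
    figure panels: per-intron length, GC density and motif-excluded GC
    content split by class x first/later, unusual-splice and CpG-presence
    proportions, and gene-level intron count / total intronic bp.

    Raw p-values are reported; ``bh_correct`` adds a Benjamini-Hochberg
    adjusted column.  Empty groups are marked absent rather than failing.
    """
    summaries = []
    props = []
    groups: dict[tuple[str, str], pd.DataFrame] = {}
    for cat in _CATEGORIES:
        for pos in ("first", "later"):
            sub = intron_df[
                (intron_df["category"] == cat) & (intron_df["position"] == pos)
            ]
            groups[(cat, pos)] = sub
            name = f"{cat}/{pos}"
            if sub.empty:
                summaries.append({"group": name, "n": 0, "absent": True})
                continue
            for metric in _INTRON_METRICS:
                s = _summarize(name, sub[metric].to_numpy())
                summaries.append({"metric": metric, **s.__dict__, "absent": False})
            for flag in _INTRON_FLAGS:
                if flag in sub and sub[flag].notna().all():
                    props.append(
                        {
                            "group": name,
                            "flag": flag,
                            "n": len(sub),
                            "proportion": float(sub[flag].mean()),
                        }
                    )

    tests = []
    for metric in _INTRON_METRICS + _INTRON_FLAGS:
        if metric not in intron_df or intron_df[metric].isna().any():
            continue
        # first vs later within each class
        for cat in _CATEGORIES:
            a, b = groups[(cat, "first")], groups[(cat, "later")]
            if len(a) and len(b):
                u, p = rank_test(a[metric].astype(float), b[metric].astype(float))
                tests.append(
                    {"metric": metric, "comparison": f"{cat}: first vs later",
                     "U": u, "p": p}
                )
        # between classes within first and within later
        for pos in ("first", "later"):
            for c1, c2 in combinations(_CATEGORIES, 2):
                a, b = groups[(c1, pos)], groups[(c2, pos)]
                if len(a) and len(b):
                    u, p = rank_test(
                        a[metric].astype(float), b[metric].astype(float)
                    )
                    tests.append(
                        {"metric": metric,
                         "comparison": f"{pos}: {c1} vs {c2}", "U": u, "p": p}
                    )
    gene_summaries = []
    for metric in _GENE_METRICS:
        for cat in _CATEGORIES:
            sub = gene_df[gene_df["category"] == cat]
            if sub.empty:
                gene_summaries.append(
                    {"metric": metric, "group": cat, "n": 0, "absent": True}
                )
                continue
            s = _summarize(cat, sub[metric].to_numpy(dtype=float))
            gene_summaries.append({"metric": metric, **s.__dict__, "absent": False})
        for c1, c2 in combinations(_CATEGORIES, 2):
            a = gene_df[gene_df["category"] == c1]
            b = gene_df[gene_df["category"] == c2]
            if len(a) and len(b):
                u, p = rank_test(a[metric].astype(float), b[metric].astype(float))
                tests.append(
                    {"metric": metric, "comparison": f"genes: {c1} vs {c2}",
                     "U": u, "p": p}
                )
    tests_df = pd.DataFrame(tests)
    if bh_correct and len(tests_df):
        tests_df["p_bh"] = _benjamini_hochberg(tests_df["p"].to_numpy())
    return {
        "intron_summaries": pd.DataFrame(summaries),
        "proportions": pd.DataFrame(props),
        "gene_summaries": pd.DataFrame(gene_summaries),
        "tests": tests_df,
    }


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i, i in enumerate(order[::-1]):
        running = min(running, p[i] * m / (m - rank_i))
        adj[i] = running
    return adj
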