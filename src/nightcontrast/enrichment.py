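"""Category-level test for coordinated direction of fold changes.

Given per-item log2(YK/SH) folds and a bin-style category map, each
category with at least ``min_size`` members is tested for divergence
from a 50/50 up/down split by a two-sided Wilcoxon signed-rank test of
the member folds against zero.  The exact null distribution is used
for n <= 25 (dynamic programming over sign assignments, equivalent to
the full 2^n enumeration and handling midranks for tied magnitudes);
above that a normal approximation with continuity and tie correction
takes over.  Zero folds are dropped before ranking.  P-values are
reported uncorrected, with a supplementary BH column; a rank-sum mode
(members versus non-members) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

EXACT_MAX_N = 25


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    n_items: int
    statistic: float
    pvalue: float
    median_fold: float
    method: str


def _signed_rank_statistic(values: np.ndarray):
    """W+ (sum of positive-value midranks) after dropping zeros."""
    values = np.asarray(values, dtype=float)
    values = values[values != 0]
    n = len(values)
    if n == 0:
        raise ValueError("no nonzero values to rank")
    ranks = stats.rankdata(np.abs(values))
    w_plus = float(ranks[values > 0].sum())
    return w_plus, ranks, n


def _exact_signed_rank_pvalue(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p via DP over the 2^n sign assignments.

    Ranks are doubled to integers so midranks (x.5 ties) stay exact;
    the distribution of 2*W+ is built by convolution, one rank at a
    time.  The two-sided p doubles the smaller tail, capped at 1.
    """
    doubled = np.round(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(dist)
        shifted[d:] = dist[: total + 1 - d]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2.0 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _approx_signed_rank_pvalue(w_plus: float, ranks: np.ndarray, n: int) -> float:
    """Normal approximation with continuity and tie correction."""
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def signed_rank_test(values, exact_max_n: int = EXACT_MAX_N):
    """Two-sided Wilcoxon signed-rank test of values against zero.

    Returns ``(w_plus, pvalue, method)`` where method is "exact" for
    n <= exact_max_n nonzero values and "approx" otherwise.
    """
    w_plus, ranks, n = _signed_rank_statistic(values)
    if n <= exact_max_n:
        return w_plus, _exact_signed_rank_pvalue(w_plus, ranks), "exact"
    return w_plus, _approx_signed_rank_pvalue(w_plus, ranks, n), "approx"


def enrich(
    folds: Mapping[str, float],
    category_map: Mapping[str, object],
    min_size: int = 3,
    mode: str = "signed_rank",
) -> pd.DataFrame:
    """Per-category direction tests over finite fold changes.

    ``category_map`` maps item id to one category label or a list of
    labels (items may be multi-assigned); items without a finite fold
    (absence-labeled genes, undetected metabolites) are excluded.
    ``mode="rank_sum"`` instead compares member folds against all
    non-member folds with a two-sided Mann-Whitney U test.
    """
    if not category_map:
        raise ValueError("empty category map")
    if mode not in ("signed_rank", "rank_sum"):
        raise ValueError("mode must be 'signed_rank' or 'rank_sum'")
    finite = {
        k: float(v)
        for k, v in folds.items()
        if isinstance(v, (int, float)) and np.isfinite(v)
    }
    members: dict[str, list[str]] = {}
    for item, cats in category_map.items():
        if item not in finite:
            continue
        labels = [cats] if isinstance(cats, str) else list(cats)
        for label in labels:
            if not label:
                raise ValueError(f"empty category label for item {item!r}")
            members.setdefault(label, []).append(item)

    rows = []
    for category in sorted(members):
        items = members[category]
        if len(items) < min_size:
            continue
        vals = np.array([finite[i] for i in items])
        if mode == "signed_rank":
            nonzero = vals[vals != 0]
            if len(nonzero) < min_size:
                continue
            statistic, p, method = signed_rank_test(vals)
            n_items = len(nonzero)
        else:
            rest = np.array([v for k, v in finite.items() if k not in set(items)])
            if len(rest) == 0:
                continue
            res = stats.mannwhitneyu(vals, rest, alternative="two-sided")
            statistic, p, method = float(res.statistic), float(res.pvalue), "rank_sum"
            n_items = len(vals)
        rows.append(
            EnrichmentResult(category, n_items, statistic, p, float(np.median(vals)), method)
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    if len(table):
        table["padj_supplementary"] = bh_adjust(table["pvalue"].to_numpy())
    return table
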