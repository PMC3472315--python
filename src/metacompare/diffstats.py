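"""Two-group differential-abundance testing with FDR control.

Each feature (taxon, gene, KO or pathway) is compared between the two host
groups with a two-sided Wilcoxon rank-sum test; raw p-values are adjusted
by the Benjamini-Hochberg step-up procedure, optionally against a family
larger than the tested set (useful when reproducing a published table that
prints only a subset of the tested features).  A feature is called
significant under the dual rule p <= 0.05 AND q <= 0.1 (both inclusive),
and figure-style star annotations follow q < 0.1 / 0.05 / 0.01.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ecology import AbundanceMatrix, log_transform

logger = logging.getLogger("metacompare")

EXACT_LIMIT = 20  # exact enumeration below this combined n, when untied


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact by enumeration when n_x + n_y <= 20 and the pooled data carry no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  Symmetric in argument order.  Two identical constant-free
    samples (equal multisets) return p = 1 with a warning, since the test
    statistic is degenerate there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if sorted(x.tolist()) == sorted(y.tolist()):
        warnings.warn("identical samples; rank-sum test is degenerate, p = 1")
        return 1.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= EXACT_LIMIT and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvalues: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, with an explicit family size.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, returned in the
    input order.  ``family_size`` (m) defaults to the number of p-values
    supplied but may be larger, which adjusts a printed subset as part of a
    bigger testing family.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValueError(f"family_size {m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def stars(q: float) -> str:
    """Figure annotation: * q<0.1, ** q<0.05, *** q<0.01."""
    if q < 0.01:
        return "***"
    if q < 0.05:
        return "**"
    if q < 0.1:
        return "*"
    return ""


def differential_table(
    matrix: AbundanceMatrix,
    family_size: int | None = None,
    alpha_p: float = 0.05,
    alpha_q: float = 0.1,
    test_on_log: bool = True,
) -> pd.DataFrame:
    """Per-feature two-group comparison in the published-table shape.

    Group means and sample SDs (n-1 denominator) are reported on the scale
    of the input matrix (normally the depth-normalized scale), while the
    rank-sum test runs on the log10(x+1)-transformed values -- a rank-based
    test is invariant to that monotone transform, so the p-values are
    unchanged, but keeping both matrices mirrors the analysis workflow.
    Features that are zero in every sample of both groups are excluded with
    a warning.  Rows come back sorted by ascending p, ties broken by
    feature id.
    """
    groups = matrix.group_names()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    sa, sb = matrix.samples_in(ga), matrix.samples_in(gb)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 samples")

    all_zero = (matrix.data[sa + sb].sum(axis=1) == 0)
    if all_zero.any():
        warnings.warn(f"excluding {int(all_zero.sum())} features that are all-zero in both groups")
    tested = matrix.data.loc[~all_zero]
    test_matrix = log_transform(matrix.copy_with(tested, raw=False)).data if test_on_log else tested

    rows = []
    for feature in tested.index:
        xa = tested.loc[feature, sa].values
        xb = tested.loc[feature, sb].values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = wilcoxon_rank_sum(test_matrix.loc[feature, sa].values,
                                  test_matrix.loc[feature, sb].values)
        mean_a, mean_b = float(np.mean(xa)), float(np.mean(xb))
        direction = ga if mean_a > mean_b else gb if mean_b > mean_a else "equal"
        rows.append(
            {
                "feature": str(feature),
                f"mean_{ga}": mean_a,
                f"sd_{ga}": float(np.std(xa, ddof=1)),
                f"mean_{gb}": mean_b,
                f"sd_{gb}": float(np.std(xb, ddof=1)),
                "p_value": p,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].values, family_size=family_size)
    table["significant"] = (table["p_value"] <= alpha_p) & (table["q_value"] <= alpha_q)
    table["stars"] = [stars(q) for q in table["q_value"]]
    table = table.sort_values(["p_value", "feature"], kind="mergesort").reset_index(drop=True)
    logger.info("differential table: %d features, %d significant",
                len(table), int(table["significant"].sum()))
    return table


def count_significant(table: pd.DataFrame) -> dict:
    """Tally significant features and their direction.

    Returns ``significant_total`` plus one ``higher_in_<group>`` count per
    group label appearing in the table's direction column.
    """
    if len(table) == 0:
        return {"significant_total": 0}
    sig = table[table["significant"]]
    out = {"significant_total": int(len(sig))}
    for grp, n in Counter(sig["direction"]).items():
        out[f"higher_in_{grp}"] = int(n)
    # ensure both directions appear even at zero
    for grp in table["direction"].unique():
        out.setdefault(f"higher_in_{grp}", 0)
    return out


def apply_dual_rule(
    p: Sequence[float], q: Sequence[float], alpha_p: float = 0.05, alpha_q: float = 0.1
) -> np.ndarray:
    """Vectorized dual significance rule: p <= alpha_p AND q <= alpha_q."""
    return (np.asarray(p) <= alpha_p) & (np.asarray(q) <= alpha_q)
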