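"""Paired nonparametric statistics and result aggregation.

Model comparisons are paired per participant: the Wilcoxon signed-rank test
(W = sum of ranks of positive differences, zeros dropped) with an exact
two-sided p-value for small samples, and Benjamini-Hochberg FDR adjustment
across a family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


class DegenerateComparisonError(ValueError):
    """All paired differences are zero."""


@dataclass
class PairedComparison:
    condition_a: str
    condition_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    W: float
    p_value: float
    p_fdr: float = float("nan")


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Returns ``(W, p)`` where W is the sum of the ranks of the positive
    differences ``a - b`` (zero differences dropped before ranking).  The
    two-sided p-value uses the exact null distribution for n <= 25 and the
    normal approximation with continuity correction for larger n.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateComparisonError("all paired differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    method = "exact" if n <= 25 else "approx"
    res = scipy.stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                               alternative="two-sided", method=method)
    return w_pos, float(res.pvalue)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return scipy.stats.false_discovery_control(p, method="bh")


def aggregate_results(reports) -> tuple[pd.DataFrame, float]:
    """Per-participant mean accuracies and their cross-participant median.

    Fold accuracies are averaged within each participant first; the median of
    those per-participant means is the headline number.  Deterministic and
    invariant to report ordering.
    """
    if not reports:
        raise ValueError("need at least one report")
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "fold_id": [r.fold_id for r in reports],
            "accuracy": [r.test_accuracy for r in reports],
        }
    )
    per_participant = (
        df.groupby("participant_id", as_index=False)["accuracy"].mean().sort_values("participant_id")
    ).reset_index(drop=True)
    median = float(per_participant["accuracy"].median())
    return per_participant, median


def compare_conditions(
    name_a: str, values_a, name_b: str, values_b
) -> PairedComparison:
    W, p = wilcoxon_signed_rank(values_a, values_b)
    return PairedComparison(
        condition_a=name_a,
        condition_b=name_b,
        values_a=np.asarray(values_a, dtype=float),
        values_b=np.asarray(values_b, dtype=float),
        W=W,
        p_value=p,
    )
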