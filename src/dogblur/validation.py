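"""Psychometric validation statistics for the blur metric.

Observer ratings (integers 0..100) are collapsed to a mean opinion score
(MOS) on [0, 1]; agreement between objective scores and MOS is measured
with the Spearman rank correlation (average ranks for ties), summarized
per degradation level and pooled across levels.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_opinion_score",
    "spearman_correlation",
    "validation_table",
    "pooled_correlation",
]


def mean_opinion_score(scores: Sequence[float]) -> float:
    """MOS on [0, 1]: mean of raw 0..100 observer scores divided by 100."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("need at least one observer score")
    if arr.min() < 0 or arr.max() > 100:
        raise ValueError("raw observer scores must lie in [0, 100]")
    return float(arr.mean() / 100.0)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("ranks are undefined for a constant sequence")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)


def validation_table(
    objective: Mapping[int, Sequence[float]],
    subjective: Mapping[int, Sequence[float]],
) -> pd.DataFrame:
    """Per-level summary of objective vs subjective agreement.

    ``objective`` maps degradation level -> per-slice metric scores Q;
    ``subjective`` maps the same levels -> per-slice MOS values aligned
    slice-for-slice.  Returns one row per level with the slice count, the
    mean of each score, and the within-level Spearman correlation.
    """
    if set(objective) != set(subjective):
        raise ValueError("objective and subjective levels must match")
    rows = []
    for level in sorted(objective):
        q = np.asarray(objective[level], dtype=np.float64)
        m = np.asarray(subjective[level], dtype=np.float64)
        if q.shape != m.shape:
            raise ValueError(f"level {level}: slice sets differ in size")
        rows.append(
            {
                "degradation_level": level,
                "n_slices": q.size,
                "avg_objective": float(q.mean()),
                "avg_subjective": float(m.mean()),
                "correlation": spearman_correlation(q, m),
            }
        )
    return pd.DataFrame(rows)


def pooled_correlation(
    objective: Mapping[int, Sequence[float]],
    subjective: Mapping[int, Sequence[float]],
) -> float:
    """Spearman correlation over all levels pooled into one sample."""
    q = np.concatenate([np.asarray(objective[k], dtype=np.float64) for k in sorted(objective)])
    m = np.concatenate([np.asarray(subjective[k], dtype=np.float64) for k in sorted(subjective)])
    return spearman_correlation(q, m)
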