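"""Validation statistics: rank agreement and paired condition comparison.

Implements the arithmetic used to validate automated REBA scoring against
human appraisers — Spearman rank correlation between score vectors,
average pairwise agreement across raters or repeated runs, and a paired
two-sided t-test comparing procedure-level scores between two conditions
(e.g. bed heights).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st


class StatsError(ValueError):
    pass


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: average ranks for ties, then the
    product-moment correlation of the ranks. Undefined (raises) when either
    vector is constant after ranking."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("spearman_rho needs two equal-length 1-D vectors")
    if len(x) < 2:
        raise StatsError("spearman_rho needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("scores must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise StatsError("correlation undefined for a constant score vector")
    rx, ry = _st.rankdata(x), _st.rankdata(y)
    if np.array_equal(rx, ry):
        return 1.0  # identical rankings: exactly 1, no round-off
    rho = _st.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class RaterScoreTable:
    """Items x raters score matrix; NaN marks items a rater did not score."""

    scores: pd.DataFrame  # index: item ids, columns: rater ids

    def __post_init__(self) -> None:
        if self.scores.shape[0] < 2:
            raise StatsError("need at least 2 items")
        vals = self.scores.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise StatsError("scores must be finite")

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "RaterScoreTable":
        """Read the ``item_id, rater_id, score`` long format."""
        df = pd.read_csv(path)
        required = {"item_id", "rater_id", "score"}
        if not required.issubset(df.columns):
            raise StatsError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        wide = df.pivot_table(
            index="item_id", columns="rater_id", values="score", aggfunc="first"
        )
        return cls(wide)

    @property
    def raters(self) -> list:
        return list(self.scores.columns)


def average_pairwise_rho(table: RaterScoreTable) -> float:
    """Unweighted mean Spearman rho over all unordered rater pairs,
    each pair restricted to the items both raters scored."""
    raters = table.raters
    if len(raters) < 2:
        raise StatsError("need at least 2 raters")
    rhos = []
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            a = table.scores[raters[i]]
            b = table.scores[raters[j]]
            both = a.notna() & b.notna()
            if both.sum() < 2:
                raise StatsError(
                    f"raters {raters[i]!r} and {raters[j]!r} share "
                    f"{int(both.sum())} scored items; need at least 2"
                )
            try:
                rhos.append(spearman_rho(a[both].to_numpy(), b[both].to_numpy()))
            except StatsError as exc:
                raise StatsError(
                    f"raters {raters[i]!r} vs {raters[j]!r}: {exc}"
                ) from exc
    return float(np.mean(rhos))


def tool_vs_raters_rho(table: RaterScoreTable, tool_scores: Sequence[float]) -> float:
    """Spearman rho between the per-item mean of the human raters and the
    automated tool's scores (tool must have scored every item)."""
    tool = np.asarray(tool_scores, dtype=float)
    if len(tool) != table.scores.shape[0]:
        raise StatsError(
            f"tool scored {len(tool)} items but the table has "
            f"{table.scores.shape[0]}"
        )
    rater_mean = table.scores.mean(axis=1, skipna=True).to_numpy()
    if np.isnan(rater_mean).any():
        raise StatsError("some items were scored by no rater")
    return spearman_rho(rater_mean, tool)


@dataclass(frozen=True)
class PairedComparison:
    condition_a: str
    condition_b: str
    n_pairs: int
    mean_a: float
    mean_b: float
    mean_difference: float  # mean_b - mean_a
    t_statistic: float
    degrees_of_freedom: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "n_pairs": self.n_pairs,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "mean_difference": self.mean_difference,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
        }


def paired_t_test(
    a: Sequence[float],
    b: Sequence[float],
    condition_a: str = "a",
    condition_b: str = "b",
) -> PairedComparison:
    """Two-sided paired t-test of b against a.

    t = mean(d) / (sd(d) / sqrt(n)) with d = b - a and the sample (n-1)
    standard deviation; p from Student's t with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired_t_test needs two equal-length 1-D vectors")
    n = len(a)
    if n < 2:
        raise StatsError("need at least 2 pairs")
    d = b - a
    if np.ptp(d) == 0.0:
        raise StatsError("differences have zero variance; t-test degenerate")
    res = _st.ttest_rel(b, a)
    return PairedComparison(
        condition_a=condition_a,
        condition_b=condition_b,
        n_pairs=n,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        mean_difference=float(np.mean(d)),
        t_statistic=float(res.statistic),
        degrees_of_freedom=n - 1,
        p_value=float(res.pvalue),
    )


def internal_agreement_rho(score_vectors: Sequence[Sequence[float]]) -> float:
    """Average pairwise Spearman rho across repeated scorings of the same
    items — the repeatability ("internal agreement") statistic. A
    deterministic pipeline yields exactly 1."""
    mat = np.asarray(score_vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise StatsError("need at least 2 repetitions of the same items")
    table = RaterScoreTable(
        pd.DataFrame(
            mat.T,
            index=[f"item_{i}" for i in range(mat.shape[1])],
            columns=[f"rep_{r}" for r in range(mat.shape[0])],
        )
    )
    return average_pairwise_rho(table)
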