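"""Group comparisons mirroring the study's statistical conventions.

Two-sided paired / unpaired t-tests (Welch by default for unpaired, pooled
selectable) and the two-sample Kolmogorov-Smirnov test, reported as tidy
:class:`ComparisonResult` records with means +/- sem and significance stars
(ns P>0.05, * P<0.05, ** P<0.01, *** P<0.001, **** P<0.0001).  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

__all__ = ["ComparisonResult", "compare_means", "compare_distributions", "summarize", "stars"]


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    statistic: float
    p_value: float
    mean: tuple[float, float]
    sem: tuple[float, float]
    paired: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError("p-value out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "group_a": self.group_labels[0],
            "group_b": self.group_labels[1],
            "n_a": self.n[0],
            "n_b": self.n[1],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "mean_a": self.mean[0],
            "mean_b": self.mean[1],
            "sem_a": self.sem[0],
            "sem_b": self.sem[1],
            "paired": self.paired,
            "stars": stars(self.p_value),
        }


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def compare_means(
    group_a,
    group_b,
    paired: bool = False,
    labels: tuple[str, str] = ("a", "b"),
    variance: str = "welch",
) -> ComparisonResult:
    """Two-sided t-test between two samples.

    Paired comparisons (two samplings from the same embryos, matched order)
    use the paired t-test; unpaired default to Welch's unequal-variance form
    (``variance="pooled"`` selects the classic pooled test).  Identical
    paired groups give statistic 0 and p = 1; a constant nonzero paired
    difference degenerates to p -> 0 and is reported as p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2 for a t-test")
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired groups must have equal length")
        diff = a - b
        if np.allclose(diff, diff[0]):
            # zero within-pair variance: degenerate, flag by exact p
            stat = 0.0 if diff[0] == 0 else np.inf * np.sign(diff[0])
            p = 1.0 if diff[0] == 0 else 0.0
        else:
            res = sps.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "paired t-test"
    else:
        res = sps.ttest_ind(a, b, equal_var=(variance == "pooled"))
        stat, p = float(res.statistic), float(res.pvalue)
        name = "unpaired t-test (Welch)" if variance == "welch" else "unpaired t-test (pooled)"
    return ComparisonResult(
        test=name,
        group_labels=labels,
        n=(len(a), len(b)),
        statistic=stat,
        p_value=p,
        mean=(float(a.mean()), float(b.mean())),
        sem=(_sem(a), _sem(b)),
        paired=paired,
    )


def compare_distributions(
    sample_a, sample_b, labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (distribution shapes)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValidationError("each sample needs n >= 5 for the KS test")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return ComparisonResult(
        test="Kolmogorov-Smirnov",
        group_labels=labels,
        n=(len(a), len(b)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean=(float(a.mean()), float(b.mean())),
        sem=(_sem(a), _sem(b)),
        paired=False,
    )


def stars(p: float) -> str:
    """Significance stars: ns P>0.05; * <0.05; ** <0.01; *** <0.001; **** <0.0001."""
    if np.isnan(p):
        return "ns"
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(values: pd.DataFrame, value_col: str, by) -> pd.DataFrame:
    """Tidy mean +/- sem summary per group."""
    rows = []
    for key, sub in values.groupby(by, sort=True):
        x = sub[value_col].to_numpy(dtype=float)
        rows.append(
            {
                ("group" if isinstance(by, str) else "group"): key,
                "n": len(x),
                "mean": float(x.mean()) if len(x) else np.nan,
                "sem": _sem(x),
            }
        )
    return pd.DataFrame(rows)
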