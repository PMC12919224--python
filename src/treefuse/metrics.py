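"""Classification metrics and across-seed aggregation.

Accuracy, generalized F1 (macro / weighted), Welch's two-sample t-test
with Welch–Satterthwaite degrees of freedom, and mean ± SD [95% CI]
summaries over repeated splits. The generalized F1 is

    F1 = Σ_c w_c · 2·precision_c·recall_c / (precision_c + recall_c)

with w_c = 1/C (macro) or n_c/n (weighted); a class that is never
predicted or never present contributes F1_c = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score

__all__ = [
    "MetricRecord", "WelchResult", "Summary",
    "accuracy", "generalized_f1", "welch_t", "summarize",
    "significance_stars", "compute_metrics",
]


@dataclass
class MetricRecord:
    accuracy: float
    f1_weighted: float
    f1_macro: float
    seed: int = 0
    variant: str = "full"

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.f1_weighted, self.f1_macro):
            if not (0.0 <= v <= 1.0):
                raise ValueError("metrics must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {"variant": self.variant, "seed": self.seed,
                "accuracy": self.accuracy, "f1_weighted": self.f1_weighted,
                "f1_macro": self.f1_macro}


class WelchResult(NamedTuple):
    t: float
    df: float
    p_two_sided: float
    p_greater: float


class Summary(NamedTuple):
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def _check(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return y_true, y_pred


def accuracy(y_true, y_pred) -> float:
    y_true, y_pred = _check(y_true, y_pred)
    return float(accuracy_score(y_true, y_pred))


def generalized_f1(y_true, y_pred, scheme: str = "macro") -> float:
    y_true, y_pred = _check(y_true, y_pred)
    if scheme not in ("macro", "weighted"):
        raise ValueError("scheme must be 'macro' or 'weighted'")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return float(f1_score(y_true, y_pred, average=scheme,
                          labels=labels, zero_division=0))


def compute_metrics(y_true, y_pred, seed: int = 0,
                    variant: str = "full") -> MetricRecord:
    return MetricRecord(
        accuracy=accuracy(y_true, y_pred),
        f1_weighted=generalized_f1(y_true, y_pred, "weighted"),
        f1_macro=generalized_f1(y_true, y_pred, "macro"),
        seed=seed, variant=variant,
    )


def welch_t(scores_a: Sequence[float], scores_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test of mean(a) vs mean(b).

    Returns the statistic, Welch–Satterthwaite degrees of freedom, the
    two-sided p-value and the one-sided p-value for "a greater than b".
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:  # identical constant samples: no evidence either way
            return WelchResult(0.0, float(na + nb - 2), 1.0, 0.5)
        raise ValueError("zero variance in both samples with unequal means")
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_two = 2.0 * stats.t.sf(abs(t), df)
    p_greater = stats.t.sf(t, df)
    return WelchResult(float(t), float(df), float(p_two), float(p_greater))


def summarize(scores: Sequence[float], confidence: float = 0.95) -> Summary:
    """Mean, sample SD and t-based confidence interval over seeds."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two scores")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2, x.size - 1) * sd / np.sqrt(x.size)
    return Summary(mean, sd, mean - half, mean + half)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
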