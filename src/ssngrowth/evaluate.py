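"""ROC/AUC evaluation with non-parametric bootstrap confidence intervals.

AUC is the Mann-Whitney statistic (probability that a random positive
outscores a random negative, ties counted 1/2).  Operating-point
metrics use the closed decision rule ``score >= threshold``.
Confidence intervals are percentile bootstrap over resamples drawn
with replacement at the nodule level; single-class resamples are
redrawn and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvalResult",
    "roc_auc",
    "operating_metrics",
    "bootstrap_ci",
    "evaluate_predictions",
]


def _check_classes(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    y = _check_classes(labels)
    return float(roc_auc_score(y, np.asarray(scores, float)))


def operating_metrics(scores, labels, threshold: float) -> dict[str, float | None]:
    """Sensitivity/specificity/PPV/NPV at decision rule score >= threshold.

    Metrics with a zero denominator are returned as ``None`` (flagged
    undefined) rather than NaN.
    """
    y = _check_classes(labels)
    pred = np.asarray(scores, float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def frac(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": frac(tp, tp + fn),
        "specificity": frac(tn, tn + fp),
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def bootstrap_ci(scores, labels, metric_fn, B: int = 2000,
                 level: float = 0.95, seed: int = 0,
                 max_redraws: int = 100_000) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric_fn(scores, labels)``.

    Resamples nodules with replacement; resamples containing a single
    class are skipped and redrawn, and the redraw count is logged on
    ``bootstrap_ci.last_redraws`` after each call.
    """
    scores = np.asarray(scores, float)
    y = _check_classes(labels)
    n = scores.size
    if n < 10:
        raise ValueError("bootstrap needs at least 10 observations")
    if B < 100:
        warnings.warn("B < 100 gives unstable percentile intervals")
    rng = np.random.default_rng(seed)
    stats_, redraws = [], 0
    while len(stats_) < B:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("resampling cannot produce both classes")
            continue
        stats_.append(metric_fn(scores[idx], yb))
    bootstrap_ci.last_redraws = redraws
    alpha = (1.0 - level) / 2.0
    # nanpercentile: a metric undefined on some resamples (e.g. PPV with
    # no predicted positives) does not poison the interval
    lo, hi = np.nanpercentile(np.asarray(stats_, float),
                              [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


bootstrap_ci.last_redraws = 0


@dataclass
class EvalResult:
    """Point estimates with 95% bootstrap CIs for one model/threshold."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float | None
    sensitivity_ci: tuple[float, float]
    specificity: float | None
    specificity_ci: tuple[float, float]
    ppv: float | None
    ppv_ci: tuple[float, float]
    npv: float | None
    npv_ci: tuple[float, float]
    threshold: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in ("auc", "sensitivity", "specificity", "ppv", "npv"):
            lo, hi = getattr(self, f"{m}_ci")
            rows.append({"metric": m, "estimate": getattr(self, m),
                         "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows)


def evaluate_predictions(scores, labels, threshold: float,
                         B: int = 2000, level: float = 0.95,
                         seed: int = 0) -> EvalResult:
    """Full operating-point report with bootstrap CIs per metric."""
    y = _check_classes(labels)
    scores = np.asarray(scores, float)
    om = operating_metrics(scores, y, threshold)

    def met(name):
        def f(s, l):
            v = operating_metrics(s, l, threshold)[name]
            return np.nan if v is None else v
        return f

    cis = {}
    for i, name in enumerate(("sensitivity", "specificity", "ppv", "npv")):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cis[name] = bootstrap_ci(scores, y, met(name), B=B, level=level,
                                     seed=seed + i + 1)
    return EvalResult(
        auc=roc_auc(scores, y),
        auc_ci=bootstrap_ci(scores, y, roc_auc, B=B, level=level, seed=seed),
        sensitivity=om["sensitivity"], sensitivity_ci=cis["sensitivity"],
        specificity=om["specificity"], specificity_ci=cis["specificity"],
        ppv=om["ppv"], ppv_ci=cis["ppv"],
        npv=om["npv"], npv_ci=cis["npv"],
        threshold=threshold,
        n_pos=int(y.sum()), n_neg=int((1 - y).sum()),
    )
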