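"""Confusion-matrix evaluation against expert labels.

Two objectives are scored.  For noise removal the positive class is
"RSN or SOZ" (an IC worth keeping); for SOZ identification the positive
class is SOZ.  From the counts the four standard metrics -- accuracy,
precision, sensitivity, specificity -- are derived, with undefined values
(zero denominators) reported as ``None`` rather than NaN.  Per-subject
metric sets aggregate to unweighted means and sample standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import NOISE, RSN, SOZ, ICLabel

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "metrics", "aggregate"]

OBJECTIVES = ("noise_removal", "soz_identification")
METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    objective: str = "noise_removal"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in METRIC_NAMES}


def _category(label) -> str:
    return label.category if isinstance(label, ICLabel) else str(label)


def confusion(
    pred, truth, objective: str, literal_tp: bool = False
) -> ConfusionCounts:
    """Count the confusion cells for one subject.

    ``pred`` and ``truth`` are aligned sequences of labels (ICLabel or
    category strings).  For SOZ identification a true positive requires
    both sides to say SOZ, keeping TP consistent with the FN definition
    (an expert-SOZ IC called non-SOZ); ``literal_tp=True`` instead counts
    any IC that both sides call SOZ-or-RSN as positive agreement.
    """
    pred = [_category(p) for p in pred]
    truth = [_category(t) for t in truth]
    if len(pred) != len(truth):
        raise ValueError(f"{len(pred)} predictions vs {len(truth)} truths")
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth):
        if objective == "noise_removal":
            p_pos = p in (RSN, SOZ)
            t_pos = t in (RSN, SOZ)
        elif literal_tp:
            p_pos = p in (RSN, SOZ)
            t_pos = t in (RSN, SOZ)
            # literal reading: agreement on SOZ-or-RSN is a TP, but FN/TN
            # still hinge on the SOZ class alone
            if t == SOZ and p != SOZ:
                fn += 1
                continue
            if t != SOZ and p != SOZ:
                tn += 1
                continue
            if p_pos and t_pos:
                tp += 1
            else:
                fp += 1
            continue
        else:
            p_pos = p == SOZ
            t_pos = t == SOZ
        if p_pos and t_pos:
            tp += 1
        elif not p_pos and not t_pos:
            tn += 1
        elif p_pos:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, objective=objective)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity from the counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return MetricSet(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


def aggregate(per_subject) -> dict:
    """Unweighted mean and sample SD of each metric across subjects.

    Undefined (None) entries are excluded, with the number of subjects
    actually contributing reported per metric.
    """
    per_subject = list(per_subject)
    if not per_subject:
        raise ValueError("at least one subject is required")
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_subject]
        defined = [v for v in vals if v is not None]
        entry = {"n": len(defined), "n_undefined": len(vals) - len(defined)}
        if defined:
            entry["mean"] = float(np.mean(defined))
            entry["sd"] = (
                float(np.std(defined, ddof=1)) if len(defined) > 1 else None
            )
        else:
            entry["mean"] = None
            entry["sd"] = None
        out[name] = entry
    return out
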