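"""Overlap indices for mask-vs-reference evaluation.

Reports the five indices conventional in brain-extraction evaluation:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), Jaccard TP/(TP+FP+FN),
Dice 2TP/(2TP+FP+FN), and the false-positive rate.  FP_Rate is defined
risk-style as FP/(TP+FN) — false positives relative to the true brain
volume — which is the convention that keeps specificity and FP_Rate
mutually consistent at realistic brain/background proportions; the
1-specificity variant is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np

from .errors import UndefinedMetricError
from .io import BinaryMask

INDEX_NAMES = ("sensitivity", "specificity", "jaccard", "dice", "fp_rate")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level confusion counts of a mask against a reference."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five indices plus the counts they derive from."""

    sensitivity: float
    specificity: float
    jaccard: float
    dice: float
    fp_rate: float
    counts: ConfusionCounts

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


MaskLike = Union[np.ndarray, BinaryMask]


def _as_bool(mask: MaskLike) -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    return data.astype(bool)


def confusion_counts(mask: MaskLike, truth: MaskLike) -> ConfusionCounts:
    """Voxel-wise confusion counts over the whole compared domain."""
    m = _as_bool(mask)
    t = _as_bool(truth)
    if m.shape != t.shape:
        raise ValueError(f"mask shape {m.shape} does not match truth shape {t.shape}")
    tp = int(np.count_nonzero(m & t))
    fp = int(np.count_nonzero(m & ~t))
    fn = int(np.count_nonzero(~m & t))
    tn = m.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(
    counts: ConfusionCounts, fp_rate_definition: str = "risk"
) -> MetricsReport:
    """Derive the five indices from confusion counts.

    ``fp_rate_definition``: ``"risk"`` for FP/(TP+FN) (default) or
    ``"one_minus_specificity"`` for FP/(FP+TN).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: reference mask is empty")
    if fp + tn == 0:
        raise UndefinedMetricError("specificity undefined: reference background is empty")
    if fp_rate_definition == "risk":
        fp_rate = fp / (tp + fn)
    elif fp_rate_definition == "one_minus_specificity":
        fp_rate = fp / (fp + tn)
    else:
        raise ValueError(f"unknown fp_rate definition {fp_rate_definition!r}")
    return MetricsReport(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        jaccard=tp / (tp + fp + fn),
        dice=2 * tp / (2 * tp + fp + fn),
        fp_rate=fp_rate,
        counts=counts,
    )


def evaluate(mask: MaskLike, truth: MaskLike, **kwargs) -> MetricsReport:
    """Shortcut: confusion counts + indices in one call."""
    return compute_metrics(confusion_counts(mask, truth), **kwargs)


def aggregate_reports(
    reports: Sequence[MetricsReport],
) -> Dict[str, Tuple[float, float]]:
    """Per-index mean and sample (n-1) standard deviation across reports.

    A single report yields sd ``nan`` (reported as absent when formatted).
    """
    if len(reports) == 0:
        raise ValueError("need at least one report to aggregate")
    out: Dict[str, Tuple[float, float]] = {}
    for name in INDEX_NAMES:
        values = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
        out[name] = (float(values.mean()), sd)
    return out


def format_aggregate(aggregate: Dict[str, Tuple[float, float]], digits: int = 3) -> str:
    """Render one 'mean(sd)' row per index, Table-style."""
    cells = []
    for name in INDEX_NAMES:
        mean, sd = aggregate[name]
        if np.isnan(sd):
            cells.append(f"{name}={mean:.{digits}f}")
        else:
            cells.append(f"{name}={mean:.{digits}f}({sd:.{digits}f})")
    return "\t".join(cells)
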