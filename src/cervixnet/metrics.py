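"""Image-level detection indices and pixel-level lesion metrics.

Image level: the healthy cervigram detection index (HCDI) is the percentage
of healthy images correctly classified, the cancer cervigram detection index
(CCDI) likewise for cancer images, and the detection index (DI) is their
unweighted mean.  Indices are reported at one-decimal precision and DI is
the mean of the reported (rounded) indices.

Pixel level, against a ground-truth lesion mask: cancer pixel sensitivity
CPS = 100*TP/(TP+FN), cancer pixel specificity CPSP = 100*TN/(TN+FP) and
cancer pixel accuracy CPA = 100*(TP+TN)/(TP+TN+FP+FN), where TP/TN count
cancer and non-cancer pixels correctly located and FP/FN the incorrectly
located ones.  Table-style aggregation is the per-column arithmetic mean
reported to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PixelMetrics:
    cps: float
    cpsp: float
    cpa: float


@dataclass(frozen=True)
class DetectionIndices:
    hcdi: float
    ccdi: float
    di: float


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of two same-shape binary masks."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def pixel_metrics(c: ConfusionCounts) -> PixelMetrics:
    if c.tp + c.fn == 0:
        raise ValueError("CPS undefined: no ground-truth cancer pixels (tp+fn = 0)")
    if c.tn + c.fp == 0:
        raise ValueError("CPSP undefined: no ground-truth non-cancer pixels (tn+fp = 0)")
    return PixelMetrics(
        cps=100.0 * c.tp / (c.tp + c.fn),
        cpsp=100.0 * c.tn / (c.tn + c.fp),
        cpa=100.0 * (c.tp + c.tn) / c.total,
    )


def _one_decimal(x: float) -> float:
    # indices are reported truncated to one decimal (98.367 -> 98.3)
    return np.floor(x * 10.0 + 1e-9) / 10.0


def detection_indices(
    healthy_correct: int,
    healthy_total: int,
    cancer_correct: int,
    cancer_total: int,
) -> DetectionIndices:
    """HCDI/CCDI/DI percentages at one-decimal reporting precision."""
    if healthy_total <= 0 or cancer_total <= 0:
        raise ValueError("class totals must be > 0")
    if healthy_correct > healthy_total or cancer_correct > cancer_total:
        raise ValueError("correct counts cannot exceed totals")
    hcdi = _one_decimal(100.0 * healthy_correct / healthy_total)
    ccdi = _one_decimal(100.0 * cancer_correct / cancer_total)
    return DetectionIndices(hcdi=hcdi, ccdi=ccdi, di=_one_decimal((hcdi + ccdi) / 2.0))


def aggregate(rows: Iterable[PixelMetrics | Sequence[float]]) -> PixelMetrics:
    """Column means of per-image (CPS, CPSP, CPA) rows, to two decimals."""
    mat = np.array(
        [(r.cps, r.cpsp, r.cpa) if isinstance(r, PixelMetrics) else tuple(r) for r in rows],
        dtype=np.float64,
    )
    if mat.size == 0:
        raise ValueError("cannot aggregate an empty row list")
    cps, cpsp, cpa = mat.mean(axis=0)
    return PixelMetrics(cps=round(cps, 2), cpsp=round(cpsp, 2), cpa=round(cpa, 2))


def report(rows: dict[str, PixelMetrics]) -> pd.DataFrame:
    """Per-image metric table with a final average row, print-ready."""
    df = pd.DataFrame(
        [(name, r.cps, r.cpsp, r.cpa) for name, r in rows.items()],
        columns=["image", "cps", "cpsp", "cpa"],
    )
    avg = aggregate(list(rows.values()))
    df.loc[len(df)] = ["average", avg.cps, avg.cpsp, avg.cpa]
    return df
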