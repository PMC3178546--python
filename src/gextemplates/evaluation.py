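"""Scoring of template predictions: per-tissue accuracy tables, 2x2
sensitivity/specificity, and mean +/- sd correlation summaries."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import SampleMetadata, metadata_index
from .template_predictor import PredictionResult

__all__ = [
    "AccuracyTable",
    "ConfusionTable2x2",
    "accuracy_report",
    "confusion_stats",
    "correlation_summary",
    "render_percent",
]


def render_percent(fraction: float, decimals: int = 2) -> float:
    """Render a fraction as a percentage rounded half away from zero.

    ``render_percent(40/45, 0) == 89.0`` — banker's rounding would give 88.
    """
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(fraction * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(value)


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Binary confusion counts with an explicit positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: str = "positive"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion table is empty")

    def swapped(self) -> "ConfusionTable2x2":
        """Swap which class is treated as positive."""
        return ConfusionTable2x2(
            tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
            positive_label=f"not:{self.positive_label}",
        )


def confusion_stats(c: ConfusionTable2x2) -> dict[str, float]:
    """Sensitivity ``tp/(tp+fn)`` and specificity ``tn/(tn+fp)``, as exact
    fractions plus integer-percent renderings."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: tp + fn == 0")
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: tn + fp == 0")
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "sensitivity_pct": render_percent(sensitivity, 0),
        "specificity_pct": render_percent(specificity, 0),
    }


@dataclass(frozen=True)
class AccuracyTable:
    """Per-tissue prediction tallies plus the overall row.

    ``per_tissue`` columns: tissue, n_samples, n_correct, accuracy
    (fraction). The overall counts are the exact column sums.
    """

    per_tissue: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"tissue", "n_samples", "n_correct", "accuracy"}
        if not required <= set(self.per_tissue.columns):
            raise ValueError(f"per_tissue must have columns {sorted(required)}")

    @property
    def overall_n(self) -> int:
        return int(self.per_tissue["n_samples"].sum())

    @property
    def overall_correct(self) -> int:
        return int(self.per_tissue["n_correct"].sum())

    @property
    def overall_accuracy(self) -> float:
        return self.overall_correct / self.overall_n

    def overall_percent(self, decimals: int = 2) -> float:
        return render_percent(self.overall_accuracy, decimals)

    def to_tsv(self, path: str | Path, decimals: int = 2) -> None:
        frame = self.per_tissue.copy()
        frame["pct_accuracy"] = [
            render_percent(a, decimals) for a in frame["accuracy"]
        ]
        overall = pd.DataFrame(
            [
                {
                    "tissue": "TOTAL",
                    "n_samples": self.overall_n,
                    "n_correct": self.overall_correct,
                    "accuracy": self.overall_accuracy,
                    "pct_accuracy": self.overall_percent(decimals),
                }
            ]
        )
        pd.concat([frame, overall], ignore_index=True).to_csv(
            path, sep="\t", index=False
        )


def accuracy_report(
    preds: Sequence[PredictionResult],
    metas: Sequence[SampleMetadata],
    label_map: Mapping[str, str] | None = None,
) -> AccuracyTable:
    """Tally correct predictions per true tissue.

    A prediction is correct when the predicted label string-equals the true
    label after applying ``label_map`` to both sides (harmonizes synonyms
    like "muscle" vs "skeletal muscle"). Every prediction must have
    metadata; tissues are ordered lexicographically.
    """
    index = metadata_index(metas)
    label_map = dict(label_map or {})

    def canon(label: str) -> str:
        return label_map.get(label, label)

    tallies: dict[str, list[int]] = {}
    for p in preds:
        meta = index.get(p.sample_id)
        if meta is None:
            raise KeyError(f"prediction for sample {p.sample_id!r} has no metadata")
        truth = canon(meta.tissue)
        counts = tallies.setdefault(truth, [0, 0])
        counts[0] += 1
        counts[1] += int(canon(p.predicted_tissue) == truth)
    if not tallies:
        raise ValueError("no predictions to score")
    rows = [
        {
            "tissue": tissue,
            "n_samples": n,
            "n_correct": correct,
            "accuracy": correct / n,
        }
        for tissue, (n, correct) in sorted(tallies.items())
    ]
    return AccuracyTable(per_tissue=pd.DataFrame(rows))


def correlation_summary(
    preds: Sequence[PredictionResult], target_tissue: str
) -> dict[str, float]:
    """Mean and sample sd (n-1) of each sample's correlation to the named
    tissue's template."""
    if len(preds) < 2:
        raise ValueError("correlation_summary needs at least 2 predictions")
    values = []
    for p in preds:
        if target_tissue not in p.correlations:
            raise KeyError(
                f"sample {p.sample_id!r} has no correlation to {target_tissue!r}"
            )
        values.append(p.correlations[target_tissue])
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)), "n": len(arr)}
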