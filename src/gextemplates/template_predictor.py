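"""Nearest-template prediction: classify a sample to the template it
correlates with most (1-nearest-neighbor over templates, Pearson or
Spearman correlation)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .expression_io import ExpressionMatrix
from .template_builder import TemplateSet

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionResult",
    "predict_sample",
    "predict_matrix",
    "deviation_score",
    "write_predictions",
    "read_predictions",
]

METHODS = ("pearson", "spearman")


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    correlations: dict[str, float]
    predicted_tissue: str
    method: str

    @property
    def best_correlation(self) -> float:
        return self.correlations[self.predicted_tissue]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return _pearson(x, y)
    # Spearman = Pearson on average ranks (standard tie convention)
    return _pearson(rankdata(x), rankdata(y))


def predict_sample(
    x: np.ndarray,
    ts: TemplateSet,
    method: str = "pearson",
    sample_id: str = "sample",
) -> PredictionResult:
    """Correlate ``x`` (aligned to ``ts.signature``) with every template
    and return the argmax tissue; ties go to the lexicographically
    smallest tissue label."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    if x.shape != (len(ts.signature),):
        raise ValueError(
            f"sample vector length {x.shape} does not match signature "
            f"length {len(ts.signature)}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"sample {sample_id!r} is constant; prediction undefined")
    correlations: dict[str, float] = {}
    for tissue, template in zip(ts.tissues, ts.vectors):
        if np.ptp(template) == 0:
            raise ValueError(f"template for tissue {tissue!r} is constant")
        correlations[tissue] = _correlate(x, template, method)
    best = max(correlations.values())
    winners = sorted(t for t, c in correlations.items() if c == best)
    if len(winners) > 1:
        logger.info(
            "sample %s: correlation tie among %s, choosing %s",
            sample_id, winners, winners[0],
        )
    return PredictionResult(
        sample_id=sample_id,
        correlations=correlations,
        predicted_tissue=winners[0],
        method=method,
    )


def predict_matrix(
    m: ExpressionMatrix,
    ts: TemplateSet,
    method: str = "pearson",
    min_gene_fraction: float = 0.9,
) -> list[PredictionResult]:
    """Predict every column of ``m``; column order is preserved.

    If some signature genes are absent from ``m``, prediction proceeds on
    the present subset provided coverage is at least ``min_gene_fraction``
    (a warning lists the missing genes); below that an error is raised.
    """
    sig_genes = list(ts.signature.gene_ids)
    present = [g for g in sig_genes if g in set(m.gene_ids)]
    coverage = len(present) / len(sig_genes)
    if coverage < min_gene_fraction:
        raise ValueError(
            f"only {len(present)}/{len(sig_genes)} signature genes present "
            f"({coverage:.1%} < required {min_gene_fraction:.0%})"
        )
    if len(present) < len(sig_genes):
        missing = sorted(set(sig_genes) - set(present))
        logger.warning(
            "predicting on %d/%d signature genes; missing: %s",
            len(present), len(sig_genes), missing,
        )
        keep = [i for i, g in enumerate(sig_genes) if g in set(present)]
        from .signature_selection import Signature

        ts = TemplateSet(
            signature=Signature(tuple(present)),
            tissues=ts.tissues,
            vectors=ts.vectors[:, keep],
            provenance=ts.provenance,
        )
    sub = m.subset_genes(present)
    return [
        predict_sample(sub.values[:, j], ts, method=method, sample_id=sample)
        for j, sample in enumerate(sub.sample_ids)
    ]


def deviation_score(
    x: np.ndarray,
    ts: TemplateSet,
    target_tissue: str,
    method: str = "pearson",
) -> float:
    """Correlation of ``x`` to the named tissue's template.

    Low values flag departure from that tissue's normal expression state
    (cancer-like or engineered samples).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    template = ts.template(target_tissue)  # KeyError on unknown tissue
    x = np.asarray(x, dtype=float)
    if x.shape != template.shape:
        raise ValueError("sample vector length does not match signature length")
    return _correlate(x, template, method)


def write_predictions(
    preds: Sequence[PredictionResult], ts: TemplateSet, path: str | Path
) -> None:
    """TSV report: sample_id, predicted_tissue, best_correlation, then one
    correlation column per template tissue."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "sample_id\tpredicted_tissue\tbest_correlation\t"
            + "\t".join(ts.tissues)
            + "\n"
        )
        for p in preds:
            fh.write(
                f"{p.sample_id}\t{p.predicted_tissue}\t"
                f"{float(p.best_correlation)!r}\t"
                + "\t".join(repr(float(p.correlations[t])) for t in ts.tissues)
                + "\n"
            )


def read_predictions(path: str | Path) -> list[PredictionResult]:
    """Read a prediction report written by :func:`write_predictions`.

    The on-disk format does not record the correlation method; results are
    tagged ``method='unspecified'``.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    header = lines[0].split("\t")
    if header[:3] != ["sample_id", "predicted_tissue", "best_correlation"]:
        raise ValueError(f"{path}: not a prediction report")
    tissues = header[3:]
    preds = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        correlations = {t: float(c) for t, c in zip(tissues, cells[3:])}
        preds.append(
            PredictionResult(
                sample_id=cells[0],
                correlations=correlations,
                predicted_tissue=cells[1],
                method="unspecified",
            )
        )
    return preds
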