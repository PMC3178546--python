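"""Developmental-trajectory analysis: regress template correlation on time
and rank tissues by the fitted slope."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, SampleMetadata, metadata_index
from .template_builder import TemplateSet
from .template_predictor import deviation_score

logger = logging.getLogger(__name__)

__all__ = ["TrajectoryFit", "fit_trajectory", "rank_template_slopes",
           "write_trajectory_report"]


@dataclass(frozen=True)
class TrajectoryFit:
    """OLS fit of correlation-to-template against time.

    ``p_value`` is the two-sided t-test probability for slope == 0
    (one-sided available via ``fit_trajectory(alternative=...)``). A
    zero-residual exact fit reports ``p_value = 0.0`` with
    ``degenerate=True`` rather than propagating an infinite t-statistic.
    """

    slope: float
    intercept: float
    p_value: float
    n: int
    tissue: str = ""
    degenerate: bool = False


def fit_trajectory(
    times: Sequence[float],
    corrs: Sequence[float],
    tissue: str = "",
    alternative: str = "two-sided",
) -> TrajectoryFit:
    """Ordinary least squares of correlation on time with a slope t-test."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(corrs, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and correlations differ in length")
    if t.size < 3:
        raise ValueError(f"need at least 3 points, got {t.size}")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and nonnegative")
    if np.ptp(t) == 0:
        raise ValueError("degenerate times: all time points identical")

    slope, intercept = np.polyfit(t, c, 1)
    residuals = c - (slope * t + intercept)
    rss = float(residuals @ residuals)
    scale = float(c @ c) if float(c @ c) > 0 else 1.0
    if rss <= 1e-24 * scale:
        logger.warning(
            "degenerate zero-residual fit%s: reporting p-value 0",
            f" for tissue {tissue!r}" if tissue else "",
        )
        return TrajectoryFit(
            slope=float(slope), intercept=float(intercept), p_value=0.0,
            n=int(t.size), tissue=tissue, degenerate=True,
        )
    res = stats.linregress(t, c, alternative=alternative)
    return TrajectoryFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=int(t.size),
        tissue=tissue,
    )


def rank_template_slopes(
    m: ExpressionMatrix,
    metas: Sequence[SampleMetadata],
    ts: TemplateSet,
    method: str = "pearson",
) -> list[TrajectoryFit]:
    """For every template tissue: correlate each time-course sample with
    that template, regress correlation on time, and return the fits sorted
    by descending slope (ties lexicographic on tissue)."""
    index = metadata_index(metas)
    sub = m.subset_genes(list(ts.signature.gene_ids))
    times = []
    for sample in sub.sample_ids:
        meta = index.get(sample)
        if meta is None:
            raise KeyError(f"sample {sample!r} has no metadata")
        if meta.time is None:
            raise ValueError(f"sample {sample!r} has no time covariate")
        times.append(meta.time)
    if len(set(times)) < 3:
        raise ValueError("need at least 3 distinct time points")

    fits = []
    for tissue in ts.tissues:
        corrs = [
            deviation_score(sub.values[:, j], ts, tissue, method=method)
            for j in range(sub.n_samples)
        ]
        fits.append(fit_trajectory(times, corrs, tissue=tissue))
    fits.sort(key=lambda f: (-f.slope, f.tissue))
    return fits


def write_trajectory_report(
    fits: Sequence[TrajectoryFit], path: str | Path
) -> None:
    """TSV: tissue, slope, intercept, p_value, n."""
    rows = [
        {
            "tissue": f.tissue,
            "slope": f.slope,
            "intercept": f.intercept,
            "p_value": f.p_value,
            "n": f.n,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
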