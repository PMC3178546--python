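"""Derivation of a compact tissue-classifying gene signature.

The pipeline: per-dataset coefficient-of-variation ranking, selection of the
top fraction, intersection of the per-dataset candidate sets, and
redundancy elimination by average-linkage hierarchical clustering under
correlation distance (one representative kept per cluster).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_io import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "compute_cv",
    "top_cv_fraction",
    "intersect_candidates",
    "remove_redundancy",
    "select_signature",
    "read_signature",
    "write_signature",
]


@dataclass(frozen=True)
class Signature:
    """Ordered, duplicate-free list of gene ids plus a provenance note."""

    gene_ids: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        if not genes:
            raise ValueError("signature must be nonempty")
        if len(set(genes)) != len(genes):
            raise ValueError("signature contains duplicate gene ids")
        object.__setattr__(self, "gene_ids", genes)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


def compute_cv(m: ExpressionMatrix, dataset_id: str = "") -> pd.DataFrame:
    """Per-gene coefficient of variation across all columns of ``m``.

    CV = sample standard deviation (n-1 denominator) / mean. Requires at
    least two samples and strictly positive gene means (CV is undefined on
    log2 data that crosses zero; shift or filter such genes upstream).

    Returns a frame with columns ``gene_id``, ``cv``, ``dataset_id``.
    """
    if m.n_samples < 2:
        raise ValueError("compute_cv requires at least 2 samples per gene")
    means = m.values.mean(axis=1)
    bad = np.asarray(means <= 0).nonzero()[0]
    if bad.size:
        names = [m.gene_ids[i] for i in bad[:10]]
        raise ValueError(
            f"{bad.size} genes have zero or negative mean (CV undefined): "
            f"{names}"
        )
    sds = m.values.std(axis=1, ddof=1)
    return pd.DataFrame(
        {"gene_id": list(m.gene_ids), "cv": sds / means, "dataset_id": dataset_id}
    )


def top_cv_fraction(table: pd.DataFrame, q: float) -> set[str]:
    """The ``ceil(q * G)`` genes with largest CV.

    Ties at the cut are broken by lexicographic gene id (smaller id wins)
    so selection is deterministic.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    if table.empty:
        raise ValueError("CV table is empty")
    k = math.ceil(q * len(table))
    ordered = table.sort_values(
        ["cv", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return set(ordered["gene_id"].iloc[:k])


def intersect_candidates(sets: Sequence[set[str]]) -> set[str]:
    """Exact intersection of per-dataset candidate gene sets."""
    if len(sets) < 2:
        raise ValueError("need at least two candidate sets to intersect")
    result = set(sets[0])
    for s in sets[1:]:
        result &= set(s)
    if not result:
        raise ValueError(
            "candidate gene sets have empty intersection; increase q"
        )
    return result


def remove_redundancy(
    m: ExpressionMatrix,
    candidates: set[str],
    corr_cut: float,
    cv_scores: Mapping[str, float] | None = None,
    representative: str = "max_cv",
) -> Signature:
    """Collapse correlated candidate genes to one representative each.

    Average-linkage hierarchical clustering of candidate genes under
    distance ``1 - Pearson(gene_i, gene_j)`` over the columns of ``m``
    (tissue-averaged profiles by convention), cut at height
    ``1 - corr_cut``. Per cluster the member with the highest ``cv_scores``
    value is kept (``representative='max_cv'``); with ``'medoid'`` the
    member with minimal summed distance to its cluster. Ties and the
    output ordering are lexicographic on gene id.
    """
    if not 0 < corr_cut < 1:
        raise ValueError(f"corr_cut must be in (0, 1), got {corr_cut}")
    if representative not in ("max_cv", "medoid"):
        raise ValueError(f"unknown representative rule {representative!r}")
    missing = candidates - set(m.gene_ids)
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {sorted(missing)[:10]}")
    genes = sorted(candidates)
    sub = m.subset_genes(genes)
    sds = sub.values.std(axis=1)
    constant = [g for g, sd in zip(genes, sds) if sd == 0]
    if constant:
        raise ValueError(
            f"candidate genes constant across columns (Pearson undefined): "
            f"{constant[:10]}"
        )
    if len(genes) == 1:
        return Signature(tuple(genes), provenance=f"corr_cut={corr_cut}")

    corr = np.corrcoef(sub.values)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=1.0 - corr_cut, criterion="distance")

    scores: Mapping[str, float]
    if cv_scores is not None:
        scores = cv_scores
    else:
        # fall back to CV computed on the clustering matrix itself
        means = sub.values.mean(axis=1)
        if np.any(means <= 0):
            raise ValueError(
                "cv_scores not supplied and clustering matrix has nonpositive "
                "gene means; pass cv_scores explicitly"
            )
        scores = dict(zip(genes, sub.values.std(axis=1, ddof=1) / means))

    chosen: list[str] = []
    for label in np.unique(labels):
        # members sorted lexicographically: max/min return the first maximal
        # element, so score ties resolve to the smallest gene id
        members = sorted(g for g, lab in zip(genes, labels) if lab == label)
        if representative == "max_cv":
            best = max(members, key=lambda g: scores.get(g, 0.0))
        else:
            idx = {g: i for i, g in enumerate(genes)}
            best = min(
                members,
                key=lambda g: sum(dist[idx[g], idx[o]] for o in members),
            )
        chosen.append(best)
    chosen.sort()
    logger.info(
        "redundancy removal: %d candidates -> %d representatives "
        "(corr_cut=%g)", len(genes), len(chosen), corr_cut
    )
    return Signature(
        tuple(chosen),
        provenance=f"corr_cut={corr_cut} representative={representative}",
    )


def select_signature(
    matrices: Sequence[ExpressionMatrix],
    metas: Sequence[SampleMetadata],
    q: float = 0.025,
    corr_cut: float = 0.85,
    cluster_profile: str = "tissue-mean",
    dataset_ids: Sequence[str] | None = None,
) -> Signature:
    """Full selection pipeline over multiple training datasets.

    Per dataset: CV ranking and top-``q`` selection; then intersection of
    the candidate sets; then redundancy removal clustered on either
    per-dataset tissue-mean profiles concatenated across datasets
    (``cluster_profile='tissue-mean'``, default) or all raw sample columns
    (``'samples'``).
    """
    from .expression_io import align_genes, metadata_index

    if len(matrices) < 2:
        raise ValueError("signature selection needs at least two datasets")
    if cluster_profile not in ("tissue-mean", "samples"):
        raise ValueError(f"unknown cluster_profile {cluster_profile!r}")
    if dataset_ids is None:
        dataset_ids = [f"dataset{i}" for i in range(len(matrices))]
    aligned = align_genes(matrices)
    index = metadata_index(metas)

    cv_frames = []
    candidate_sets = []
    for m, ds in zip(aligned, dataset_ids):
        table = compute_cv(m, dataset_id=ds)
        cv_frames.append(table)
        candidate_sets.append(top_cv_fraction(table, q))
    candidates = intersect_candidates(candidate_sets)
    mean_cv = (
        pd.concat(cv_frames).groupby("gene_id")["cv"].mean().to_dict()
    )

    if cluster_profile == "tissue-mean":
        cluster_m = _tissue_mean_columns(aligned, metas, index, dataset_ids)
    else:
        frames = [m.to_frame() for m in aligned]
        for frame, ds in zip(frames, dataset_ids):
            frame.columns = [f"{ds}:{c}" for c in frame.columns]
        cluster_m = ExpressionMatrix.from_frame(pd.concat(frames, axis=1))

    sig = remove_redundancy(cluster_m, candidates, corr_cut, cv_scores=mean_cv)
    provenance = (
        f"q={q} corr_cut={corr_cut} cluster_profile={cluster_profile} "
        f"datasets={','.join(dataset_ids)} "
        f"candidates={len(candidates)} selected={len(sig)}"
    )
    return Signature(sig.gene_ids, provenance=provenance)


def _tissue_mean_columns(
    aligned: Sequence[ExpressionMatrix],
    metas: Sequence[SampleMetadata],
    index: Mapping[str, SampleMetadata],
    dataset_ids: Sequence[str],
) -> ExpressionMatrix:
    """One column per (dataset, tissue): the tissue's mean profile."""
    columns: dict[str, np.ndarray] = {}
    genes = aligned[0].gene_ids
    for m, ds in zip(aligned, dataset_ids):
        by_tissue: dict[str, list[int]] = {}
        for j, sample in enumerate(m.sample_ids):
            meta = index.get(sample)
            if meta is None:
                raise KeyError(f"sample {sample!r} has no metadata")
            by_tissue.setdefault(meta.tissue, []).append(j)
        for tissue in sorted(by_tissue):
            columns[f"{ds}:{tissue}"] = m.values[:, by_tissue[tissue]].mean(axis=1)
    names = sorted(columns)
    values = np.column_stack([columns[c] for c in names])
    return ExpressionMatrix(genes, tuple(names), values)


# ---------------------------------------------------------------------------
# signature I/O (one gene per line, '#' comments carry provenance)


def write_signature(sig: Signature, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if sig.provenance:
            for line in sig.provenance.splitlines():
                fh.write(f"# {line}\n")
        for gene in sig.gene_ids:
            fh.write(gene + "\n")


def read_signature(path: str | Path) -> Signature:
    path = Path(path)
    provenance: list[str] = []
    genes: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance.append(line.lstrip("#").strip())
        else:
            genes.append(line)
    return Signature(tuple(genes), provenance="\n".join(provenance))
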