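"""Construction of per-tissue expression templates from training data.

A template set holds, for each tissue, the expected log2 expression of
every signature gene. The default estimator is a two-level equal-weight
mean: average within each (dataset, tissue), then average the per-dataset
means — so no single large dataset dominates. Pooled averaging across all
samples is available as an option.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata, metadata_index
from .signature_selection import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSet",
    "build_templates",
    "template_similarity",
    "read_templates",
    "write_templates",
]


@dataclass(frozen=True)
class TemplateSet:
    """Tissue -> expected signature-gene expression vectors.

    ``vectors`` has one row per tissue (ordered as ``tissues``) and one
    column per signature gene (ordered as ``signature.gene_ids``).
    """

    signature: Signature
    tissues: tuple[str, ...]
    vectors: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tissues = tuple(str(t) for t in self.tissues)
        vectors = np.asarray(self.vectors, dtype=float)
        if len(set(tissues)) != len(tissues):
            raise ValueError("duplicate tissue labels in template set")
        if vectors.shape != (len(tissues), len(self.signature)):
            raise ValueError(
                f"vectors shape {vectors.shape} != "
                f"({len(tissues)} tissues, {len(self.signature)} genes)"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("template vectors contain non-finite values")
        object.__setattr__(self, "tissues", tissues)
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def template(self, tissue: str) -> np.ndarray:
        try:
            i = self.tissues.index(tissue)
        except ValueError:
            raise KeyError(f"unknown tissue {tissue!r}") from None
        return self.vectors[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.vectors,
            index=list(self.tissues),
            columns=list(self.signature.gene_ids),
        )


def build_templates(
    matrices: Sequence[ExpressionMatrix],
    metas: Sequence[SampleMetadata],
    sig: Signature,
    mode: str = "dataset-mean",
) -> TemplateSet:
    """Average training samples into one template per tissue.

    ``mode='dataset-mean'`` (default): mean within (dataset, tissue), then
    equal-weight mean of the per-dataset means. ``mode='pooled'``: plain
    mean over all samples of the tissue regardless of dataset. Tissues not
    present in every dataset are dropped with a warning; output tissues are
    ordered lexicographically.
    """
    if mode not in ("dataset-mean", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    if not matrices:
        raise ValueError("no training matrices given")
    index = metadata_index(metas)
    subs = [m.subset_genes(list(sig.gene_ids)) for m in matrices]

    # per matrix: tissue -> sample column indices
    groupings: list[dict[str, list[int]]] = []
    dataset_ids: list[str] = []
    for m in subs:
        groups: dict[str, list[int]] = {}
        ds_seen: set[str] = set()
        for j, sample in enumerate(m.sample_ids):
            meta = index.get(sample)
            if meta is None:
                raise KeyError(f"sample {sample!r} has no metadata")
            groups.setdefault(meta.tissue, []).append(j)
            ds_seen.add(meta.dataset_id)
        groupings.append(groups)
        dataset_ids.append(",".join(sorted(ds_seen)))

    shared = set(groupings[0])
    union = set(groupings[0])
    for groups in groupings[1:]:
        shared &= set(groups)
        union |= set(groups)
    dropped = union - shared
    if dropped:
        logger.warning(
            "dropping tissues absent from some training dataset: %s",
            sorted(dropped),
        )
    if not shared:
        raise ValueError("no tissue is present in every training dataset")

    tissues = sorted(shared)
    rows = []
    for tissue in tissues:
        if mode == "dataset-mean":
            per_dataset = [
                m.values[:, groups[tissue]].mean(axis=1)
                for m, groups in zip(subs, groupings)
            ]
            rows.append(np.mean(per_dataset, axis=0))
        else:
            pooled = np.concatenate(
                [m.values[:, groups[tissue]] for m, groups in zip(subs, groupings)],
                axis=1,
            )
            rows.append(pooled.mean(axis=1))
    return TemplateSet(
        signature=sig,
        tissues=tuple(tissues),
        vectors=np.vstack(rows),
        provenance=tuple(dataset_ids) + (f"mode={mode}",),
    )


def template_similarity(ts: TemplateSet) -> pd.DataFrame:
    """Pairwise Pearson correlation between tissue templates.

    Diagnostic for near-duplicate tissues; symmetric with unit diagonal.
    """
    if ts.n_tissues < 2:
        raise ValueError("template similarity needs at least two tissues")
    sds = ts.vectors.std(axis=1)
    constant = [t for t, sd in zip(ts.tissues, sds) if sd == 0]
    if constant:
        raise ValueError(f"constant template vector for tissue(s): {constant}")
    corr = np.corrcoef(ts.vectors)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(ts.tissues), columns=list(ts.tissues))


# ---------------------------------------------------------------------------
# template I/O: TSV (tissue rows x gene columns) + JSON provenance sidecar


def write_templates(ts: TemplateSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("tissue\t" + "\t".join(ts.signature.gene_ids) + "\n")
        for tissue, row in zip(ts.tissues, ts.vectors):
            fh.write(tissue + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "provenance": list(ts.provenance),
                "signature_provenance": ts.signature.provenance,
            },
            indent=2,
        ),
        encoding="utf-8",
    )


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    lines = [
        ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    header = lines[0].split("\t")
    if header[0] != "tissue":
        raise ValueError(f"{path}: expected 'tissue' header column")
    genes = tuple(header[1:])
    tissues: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        tissues.append(cells[0])
        rows.append([float(c) for c in cells[1:]])
    provenance: tuple[str, ...] = ()
    sig_provenance = ""
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        blob = json.loads(sidecar.read_text(encoding="utf-8"))
        provenance = tuple(blob.get("provenance", ()))
        sig_provenance = blob.get("signature_provenance", "")
    return TemplateSet(
        signature=Signature(genes, provenance=sig_provenance),
        tissues=tuple(tissues),
        vectors=np.array(rows, dtype=float),
        provenance=provenance,
    )
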