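"""Synthetic expression compendia with the structure the template method
assumes: tissue-specific mean profiles shared across datasets, per-dataset
batch offsets, Gaussian per-cell noise, a minority of high-variance
signature-like genes amid low-variance background, plus developmental
trajectories and cancer-like perturbations.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawns, one independent stream per model
component, so outputs are bit-reproducible and adding samples to one
component never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .expression_io import ExpressionMatrix, SampleMetadata
from .signature_selection import Signature
from .template_builder import TemplateSet

__all__ = [
    "SimConfig",
    "generate_compendium",
    "generate_trajectory",
    "generate_perturbed",
    "truth_templates",
]


@dataclass(frozen=True)
class SimConfig:
    """Planted-model parameters for a multi-dataset compendium.

    The cell value for gene g, tissue t, dataset k is
    ``b_g + e_{g,t} * [g is signature] + d_{g,k} + noise`` with
    ``b_g ~ N(baseline_mean, 1)``, tissue effect ``e_{g,t} ~ N(0,
    tissue_effect_sd)`` fixed across datasets, batch offset ``d_{g,k} ~
    N(0, batch_sd)`` per (gene, dataset), and cell noise ``N(0, noise_sd)``.
    """

    n_tissues: int = 24
    n_genes: int = 5000
    n_signature: int = 60
    n_datasets: int = 3
    samples_per_tissue_per_dataset: int = 1
    tissue_effect_sd: float = 2.0
    batch_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tissues": self.n_tissues,
            "n_genes": self.n_genes,
            "n_signature": self.n_signature,
            "n_datasets": self.n_datasets,
            "samples_per_tissue_per_dataset": self.samples_per_tissue_per_dataset,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature cannot exceed n_genes")
        for name in ("tissue_effect_sd", "batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _gene_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_compendium(
    cfg: SimConfig,
) -> tuple[list[ExpressionMatrix], list[SampleMetadata], dict]:
    """Simulate ``cfg.n_datasets`` expression matrices plus metadata.

    Signature genes are the first ``cfg.n_signature`` gene ids (recorded in
    the truth record together with the per-tissue expected profiles, i.e.
    baseline + tissue effect, which exclude batch offsets and noise).
    """
    genes = _gene_labels(cfg.n_genes)
    tissues = [f"tissue{t:02d}" for t in range(cfg.n_tissues)]
    signature_genes = genes[: cfg.n_signature]

    root = np.random.SeedSequence(cfg.seed)
    ss_baseline, ss_effects, ss_batch, ss_noise = root.spawn(4)
    baseline = np.random.default_rng(ss_baseline).normal(
        cfg.baseline_mean, 1.0, size=cfg.n_genes
    )
    effects = np.zeros((cfg.n_genes, cfg.n_tissues))
    effects[: cfg.n_signature] = np.random.default_rng(ss_effects).normal(
        0.0, cfg.tissue_effect_sd, size=(cfg.n_signature, cfg.n_tissues)
    )
    batch_rng = np.random.default_rng(ss_batch)
    noise_rngs = [
        np.random.default_rng(s) for s in ss_noise.spawn(cfg.n_datasets)
    ]

    matrices: list[ExpressionMatrix] = []
    metas: list[SampleMetadata] = []
    reps = cfg.samples_per_tissue_per_dataset
    for k in range(cfg.n_datasets):
        dataset_id = f"dataset{k}"
        offsets = batch_rng.normal(0.0, cfg.batch_sd, size=cfg.n_genes)
        clean = baseline[:, None] + effects + offsets[:, None]  # genes x tissues
        expanded = np.repeat(clean, reps, axis=1)
        noise = noise_rngs[k].normal(0.0, cfg.noise_sd, size=expanded.shape)
        values = expanded + noise
        sample_ids = []
        for t, tissue in enumerate(tissues):
            for r in range(reps):
                sample = f"{dataset_id}_{tissue}_s{r}"
                sample_ids.append(sample)
                metas.append(
                    SampleMetadata(
                        sample_id=sample, tissue=tissue, dataset_id=dataset_id
                    )
                )
        matrices.append(
            ExpressionMatrix(tuple(genes), tuple(sample_ids), values)
        )

    truth = {
        "signature_genes": list(signature_genes),
        "tissues": tissues,
        "expected_profiles": {
            tissue: (baseline + effects[:, t]).tolist()
            for t, tissue in enumerate(tissues)
        },
        "config": {
            "n_tissues": cfg.n_tissues,
            "n_genes": cfg.n_genes,
            "n_signature": cfg.n_signature,
            "n_datasets": cfg.n_datasets,
            "samples_per_tissue_per_dataset": reps,
            "tissue_effect_sd": cfg.tissue_effect_sd,
            "batch_sd": cfg.batch_sd,
            "noise_sd": cfg.noise_sd,
            "baseline_mean": cfg.baseline_mean,
            "seed": cfg.seed,
        },
    }
    return matrices, metas, truth


def truth_templates(truth: dict) -> TemplateSet:
    """Template set built from a truth record's noise-free signature
    profiles (generator ground truth, handy for oracle tests)."""
    sig_genes = truth["signature_genes"]
    n_sig = len(sig_genes)
    tissues = sorted(truth["tissues"])
    vectors = np.array(
        [truth["expected_profiles"][t][:n_sig] for t in tissues]
    )
    return TemplateSet(
        signature=Signature(tuple(sig_genes), provenance="synthetic truth"),
        tissues=tuple(tissues),
        vectors=vectors,
        provenance=("synthetic-truth",),
    )


def generate_trajectory(
    ts: TemplateSet,
    target_tissue: str,
    progenitor_vector: np.ndarray,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    mixing: str = "linear",
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Interpolate from a progenitor profile toward a tissue template.

    The sample at time t is ``(1 - w(t)) * progenitor + w(t) * template``
    plus N(0, noise_sd) per gene, with ``w(t) = t / max(times)`` for
    ``mixing='linear'`` or a logistic ramp for ``mixing='logistic'``.
    """
    if mixing not in ("linear", "logistic"):
        raise ValueError(f"unknown mixing {mixing!r}")
    times = [float(t) for t in times]
    if not times:
        raise ValueError("times must be nonempty")
    if min(times) < 0:
        raise ValueError("times must be nonnegative")
    tmax = max(times)
    if tmax <= 0:
        raise ValueError("max(times) must be positive")
    template = ts.template(target_tissue)
    progenitor = np.asarray(progenitor_vector, dtype=float)
    if progenitor.shape != template.shape:
        raise ValueError(
            f"progenitor length {progenitor.shape} does not match signature "
            f"length {template.shape}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    columns = []
    metas = []
    sample_ids = []
    for i, t in enumerate(times):
        if mixing == "linear":
            w = t / tmax
        else:
            w = 1.0 / (1.0 + np.exp(-10.0 * (t / tmax - 0.5)))
        x = (1.0 - w) * progenitor + w * template
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=x.shape)
        sample = f"traj_t{i:03d}"
        sample_ids.append(sample)
        columns.append(x)
        metas.append(
            SampleMetadata(
                sample_id=sample,
                tissue=target_tissue,
                dataset_id="trajectory",
                time=t,
            )
        )
    matrix = ExpressionMatrix(
        ts.signature.gene_ids, tuple(sample_ids), np.column_stack(columns)
    )
    return matrix, metas


def generate_perturbed(
    ts: TemplateSet,
    tissue: str,
    fraction: float,
    shift_sd: float,
    n: int,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> ExpressionMatrix:
    """Cancer-like samples: the tissue template with a random subset of
    ``ceil(fraction * |signature|)`` genes shifted by N(0, shift_sd), plus
    optional baseline noise on every gene."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if shift_sd < 0 or noise_sd < 0:
        raise ValueError("shift_sd and noise_sd must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    template = ts.template(tissue)
    n_genes = template.size
    n_shift = int(np.ceil(fraction * n_genes))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    columns = []
    sample_ids = []
    for i in range(n):
        x = template.copy()
        hit = rng.choice(n_genes, size=n_shift, replace=False)
        x[hit] += rng.normal(0.0, shift_sd, size=n_shift)
        if noise_sd > 0:
            x += rng.normal(0.0, noise_sd, size=n_genes)
        columns.append(x)
        sample_ids.append(f"perturbed_{tissue}_{i:03d}")
    return ExpressionMatrix(
        ts.signature.gene_ids, tuple(sample_ids), np.column_stack(columns)
    )
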