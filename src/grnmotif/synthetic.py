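"""Synthetic scRNA-seq-like data with planted regulatory structure.

Each planted TF gets a smooth latent profile along the (pseudo-) temporal
cell axis; its targets track that profile inside per-TF synchronization
spans (latent = coupling * TF latent + (1 - coupling) * independent latent)
and follow an independent latent elsewhere.  Latents are mixed on the log
scale — where expression synchrony lives — and exponentiated with a
realistic multi-order-of-magnitude dynamic range, so the planted
correlation survives the technical noise the way synchronous spans are
visible in real single-cell data.  Unrelated noise genes carry independent
latents.  Log-normal multiplicative noise and i.i.d. dropout zeros are
applied on top — a minimal model of sparse, bursty single-cell counts, with
no library-size or batch structure.

The span metadata is returned with the data so that interpretability tests
can check recovered sub-vector importance against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .io_data import EdgeList, ExpressionMatrix
from .labels import (
    PairSample,
    Task,
    build_causality_samples,
    build_gene_gene_samples,
    build_interaction_samples,
)
from .training import SplitSpec, make_tf_folds, split_gene_gene

DEFAULT_SPAN_FRACTION = 0.4  # span length as a fraction of the cell axis
LATENT_TAU = 25.0  # correlation time (cells) of the latent expression process


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_tfs: int = 5
    targets_per_tf: int = 20
    n_noise_genes: int = 100
    k_cells: int = 500
    sync_spans: dict[int, list[tuple[int, int]]] | None = None  # per-TF index
    coupling: float = 0.8
    dropout_rate: float = 0.3
    noise_sd: float = 0.3
    base_profile: Literal["random_walk", "pulse", "constant"] = "random_walk"
    base_mean: float = 5.0
    amplitude: float = 1.5  # log-scale sd of the latent profile (dynamic range)
    tf_scale: float = 1.0  # >1 gives TFs a higher expression scale
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.sync_spans is not None:
            for spans in self.sync_spans.values():
                for start, end in spans:
                    if not 0 <= start < end <= self.k_cells:
                        raise ValueError(
                            f"span ({start}, {end}) outside [0, {self.k_cells})"
                        )


def _latent_profile(
    rng: np.random.Generator,
    spec: SimulationSpec,
    pulse_span: tuple[int, int] | None = None,
) -> np.ndarray:
    """Standardized (mean 0, sd 1) latent log-scale profile along the cells.

    For pulse profiles, ``pulse_span`` pins the active phase; a TF's pulse is
    pinned to its synchronization span so the regulatory program and the
    gene's active phase coincide, as in phase-specific regulation.
    """
    k = spec.k_cells
    if spec.base_profile == "constant":
        return np.zeros(k)
    if spec.base_profile == "pulse":
        if pulse_span is None:
            length = k // 4
            start = int(rng.integers(0, max(k - length, 1)))
            pulse_span = (start, start + length)
        z = -np.ones(k)
        z[pulse_span[0] : pulse_span[1]] = 1.0
        return (z - z.mean()) / (z.std() + 1e-12)
    # random_walk: mean-reverting (Ornstein-Uhlenbeck) walk, standardized.
    # A plain cumulative-sum walk is nonstationary and two independent walks
    # correlate spuriously; mean reversion keeps profiles bounded the way
    # expression trajectories are, with correlation time ~LATENT_TAU cells.
    rho = np.exp(-1.0 / LATENT_TAU)
    eps = rng.normal(0.0, 1.0, size=k)
    z = np.empty(k)
    z[0] = eps[0]
    for t in range(1, k):
        z[t] = rho * z[t - 1] + np.sqrt(1.0 - rho**2) * eps[t]
    w = 5
    smooth = np.convolve(z, np.ones(w) / w, mode="same")
    return (smooth - smooth.mean()) / (smooth.std() + 1e-12)


def _expression(latent: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Map a latent profile to positive expression with log-normal spread."""
    return spec.base_mean * np.exp(spec.amplitude * latent)


def _default_spans(
    rng: np.random.Generator, spec: SimulationSpec
) -> dict[int, list[tuple[int, int]]]:
    length = max(1, int(round(DEFAULT_SPAN_FRACTION * spec.k_cells)))
    spans = {}
    for t in range(spec.n_tfs):
        start = int(rng.integers(0, spec.k_cells - length + 1))
        spans[t] = [(start, start + length)]
    return spans


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, EdgeList, dict[str, list[tuple[int, int]]]]:
    """Generate the matrix, the planted edge list and the true spans."""
    rng = np.random.default_rng(spec.seed)
    spans = spec.sync_spans if spec.sync_spans is not None else _default_spans(rng, spec)
    k = spec.k_cells
    gene_ids: list[str] = []
    clean_rows: list[np.ndarray] = []
    edges: set[tuple[str, str]] = set()
    span_by_tf: dict[str, list[tuple[int, int]]] = {}

    tf_latents = []
    for t in range(spec.n_tfs):
        tf_id = f"TF{t}"
        tf_spans = spans.get(t, [])
        z = _latent_profile(rng, spec, pulse_span=tf_spans[0] if tf_spans else None)
        tf_latents.append(z)
        gene_ids.append(tf_id)
        clean_rows.append(_expression(z, spec) * spec.tf_scale)
        span_by_tf[tf_id] = list(spans.get(t, []))
    for t in range(spec.n_tfs):
        tf_id = f"TF{t}"
        in_span = np.zeros(k, dtype=bool)
        for start, end in span_by_tf[tf_id]:
            in_span[start:end] = True
        for j in range(spec.targets_per_tf):
            tg_id = f"TF{t}_TG{j:02d}"
            own = _latent_profile(rng, spec)
            z = np.where(
                in_span,
                spec.coupling * tf_latents[t] + (1.0 - spec.coupling) * own,
                own,
            )
            gene_ids.append(tg_id)
            clean_rows.append(_expression(z, spec))
            edges.add((tf_id.lower(), tg_id.lower()))
    for j in range(spec.n_noise_genes):
        gene_ids.append(f"NOISE{j:03d}")
        clean_rows.append(_expression(_latent_profile(rng, spec), spec))

    values = np.stack(clean_rows)
    values = values * np.exp(rng.normal(0.0, spec.noise_sd, size=values.shape))
    if spec.dropout_rate > 0:
        values = values * (rng.random(values.shape) >= spec.dropout_rate)
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=[f"C{c:04d}" for c in range(k)],
        values=values,
        cell_order_kind="pseudotime",
    )
    net = EdgeList(edges=edges)
    return matrix, net, {tf.lower(): sp for tf, sp in span_by_tf.items()}


@dataclass
class TaskFixture:
    matrix: ExpressionMatrix
    network: EdgeList
    spans: dict[str, list[tuple[int, int]]]
    samples: list[PairSample]
    splits: list[SplitSpec] = field(default_factory=list)


def make_task_fixture(spec: SimulationSpec, task: Task) -> TaskFixture:
    """Ready-to-train fixture: data + samples + the task's split(s).

    ``gene_gene`` gets the stratified 3:1:1 split; ``interaction`` and
    ``causality`` get TF-disjoint 3-fold cross-validation splits.  Causality
    fixtures should use ``tf_scale > 1`` so regulator and target profiles are
    distinguishable by scale (the direction cue the classifier can learn).
    """
    if task == "causality" and spec.tf_scale <= 1.0:
        spec = replace(spec, tf_scale=3.0)
    matrix, net, spans = simulate_dataset(spec)
    if task == "gene_gene":
        samples, _ = build_gene_gene_samples(net, matrix)
        splits = [split_gene_gene(samples, seed=spec.seed)]
    elif task == "interaction":
        samples = build_interaction_samples(net, matrix, seed=spec.seed)
        splits = make_tf_folds(samples, seed=spec.seed)
    elif task == "causality":
        samples = build_causality_samples(net, matrix)
        splits = make_tf_folds(samples, seed=spec.seed)
    else:
        raise ValueError(f"unknown task {task!r}")
    return TaskFixture(matrix, net, spans, samples, splits)
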