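"""Gene-expression-motif (GEM) pair encoding.

A gene's expression vector over k ordered cells is split into contiguous
windows of s cells; for a gene pair the two genes' windows covering the same
cells are concatenated position-wise, giving a sequence of L = ceil(k/s)
sub-vectors of width 2s.  The first half of every sub-vector always comes
from the regulator-slot gene, so the encoding of (a, b) and of (b, a) differ
by swapping halves — the asymmetry that makes direction calling learnable.

When s does not divide k the trailing window is zero-padded so no cell is
discarded.  Encoding is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .io_data import ExpressionMatrix
from .labels import PairSample


@dataclass
class GEMTensor:
    """Encoded pair: ``seq`` has shape (L, 2s); halves are gene_a then gene_b."""

    pair: tuple[str, str]
    window: int
    seq: np.ndarray

    @property
    def L(self) -> int:
        return self.seq.shape[0]


def split_subvectors(x: np.ndarray, s: int) -> np.ndarray:
    """Split ``x`` (length k) into ceil(k/s) windows of s, zero-padding the last."""
    if s < 1:
        raise ValueError("window size s must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    k = x.shape[0]
    if k < 1:
        raise ValueError("expression vector must be non-empty")
    L = ceil(k / s)
    padded = np.zeros(L * s, dtype=np.float64)
    padded[:k] = x
    return padded.reshape(L, s)


def encode_pair(
    xa: np.ndarray, xb: np.ndarray, s: int, pair: tuple[str, str] = ("a", "b")
) -> GEMTensor:
    """Concatenate the two genes' aligned windows into the model input."""
    xa = np.asarray(xa, dtype=np.float64)
    xb = np.asarray(xb, dtype=np.float64)
    if xa.shape != xb.shape:
        raise ValueError(
            f"length mismatch between {pair[0]!r} ({xa.shape[0]}) "
            f"and {pair[1]!r} ({xb.shape[0]})"
        )
    seq = np.concatenate([split_subvectors(xa, s), split_subvectors(xb, s)], axis=1)
    return GEMTensor(pair=pair, window=s, seq=seq)


def encode_samples(
    samples: list[PairSample],
    m: ExpressionMatrix,
    s: int,
    log1p: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a sample list into a batch tensor (N, L, 2s) and label vector.

    ``log1p`` applies the default pre-encoding transform; cells are consumed
    in matrix column order, so pseudo-time/time-course matrices must already
    be column-sorted (a warning is the io layer's concern).
    """
    if s > m.n_cells:
        raise ValueError(f"window {s} exceeds cell count {m.n_cells}")
    values = np.log1p(m.values) if log1p else m.values
    X = np.empty((len(samples), ceil(m.n_cells / s), 2 * s), dtype=np.float64)
    y = np.empty(len(samples), dtype=np.float64)
    for i, smp in enumerate(samples):
        xa = values[m.row_index(smp.gene_a)]
        xb = values[m.row_index(smp.gene_b)]
        X[i] = encode_pair(xa, xb, s, (smp.gene_a, smp.gene_b)).seq
        y[i] = smp.label
    return X, y
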