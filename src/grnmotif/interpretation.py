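"""Sub-vector importance probing.

The trained classification head is applied to each position of the encoder
output individually (bypassing the average pooling), giving a per-sub-vector
classification probability; the argmax position is the pair's most
influential window of cells.  Tallying the argmax across all samples of one
TF shows which span of the (pseudo-)temporal axis drives that TF's calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gem import GEMTensor, encode_samples
from .io_data import ExpressionMatrix
from .labels import PairSample
from .model import MotifTransformer


@dataclass
class ImportanceProfile:
    pair: tuple[str, str]
    probs: np.ndarray  # (L,) per-position classification probability
    argmax_position: int


def subvector_probabilities(
    model: MotifTransformer, pair: GEMTensor
) -> ImportanceProfile:
    """Per-position probabilities via the classification-head probe.

    Argmax ties break toward the earliest position.
    """
    if pair.window != model.config.window:
        raise ValueError("window mismatch between model and tensor")
    enc = model.encoder_outputs(pair.seq[None])[0]  # (L, d_model)
    probs = model.head_probs(enc)
    return ImportanceProfile(
        pair=pair.pair, probs=probs, argmax_position=int(np.argmax(probs))
    )


def batch_profiles(
    model: MotifTransformer,
    samples: list[PairSample],
    m: ExpressionMatrix,
    log1p: bool = True,
) -> list[ImportanceProfile]:
    X, _ = encode_samples(samples, m, model.config.window, log1p=log1p)
    enc = model.encoder_outputs(X)  # (B, L, d_model)
    probs = model.head_probs(enc)  # (B, L)
    return [
        ImportanceProfile(
            pair=(s.gene_a, s.gene_b), probs=probs[i],
            argmax_position=int(np.argmax(probs[i])),
        )
        for i, s in enumerate(samples)
    ]


def tf_importance_tally(
    model: MotifTransformer,
    samples: list[PairSample],
    m: ExpressionMatrix,
    log1p: bool = True,
    pooled: bool = False,
) -> np.ndarray:
    """Fraction of samples whose most important sub-vector is each position.

    Meant for the samples of one TF group; pass ``pooled=True`` to tally
    across several groups without the mixing warning.
    """
    if not samples:
        raise ValueError("need at least one sample")
    tfs = {s.tf_group for s in samples}
    if len(tfs) > 1 and not pooled:
        warnings.warn(f"tally mixes {len(tfs)} TF groups", stacklevel=2)
    profiles = batch_profiles(model, samples, m, log1p=log1p)
    L = profiles[0].probs.shape[0]
    counts = np.bincount([p.argmax_position for p in profiles], minlength=L)
    return counts / counts.sum()


def save_profiles(profiles: list[ImportanceProfile], path) -> None:
    rows = [
        (p.pair[0], p.pair[1], pos, float(prob))
        for p in profiles
        for pos, prob in enumerate(p.probs)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "position", "probability"]).to_csv(
        path, sep="\t", index=False
    )


def save_tally(tally: np.ndarray, path) -> None:
    pd.DataFrame(
        {"position": np.arange(len(tally)), "fraction": tally}
    ).to_csv(path, sep="\t", index=False)


def plot_profiles(profiles: list[ImportanceProfile], path) -> None:
    """Heatmap of per-position probabilities (pairs x positions) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.stack([p.probs for p in profiles])
    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(profiles))))
    im = ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xlabel("sub-vector position")
    ax.set_ylabel("gene pair")
    fig.colorbar(im, ax=ax, label="P(interaction)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
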