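"""Data-splitting strategies and the optimization loop.

Two regimes:

* network reconstruction — a stratified 3:1:1 train/validation/test split of
  the gene-pair samples, preserving the positive:negative ratio in each part;
* TF-gene prediction — 3-fold cross-validation with folds built on whole TF
  groups, so every sample sharing a regulator lands in exactly one of
  training or testing (the anti-leakage guarantee), with 20% of each fold's
  training samples carved out as validation.

Training minimizes binary cross-entropy with Adam, logging per-epoch train /
validation loss and validation AUROC; the checkpoint with the best validation
AUROC is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

from .evaluation import roc_pr_curves
from .gem import encode_samples
from .io_data import ExpressionMatrix
from .labels import PairSample
from .model import ModelConfig, MotifTransformer


@dataclass
class SplitSpec:
    """Disjoint index lists into one PairSample list."""

    train: list[int]
    val: list[int]
    test: list[int]
    strategy: Literal["gene_gene_311", "tf_3fold"]
    fold_id: int | None = None
    seed: int = 0


def split_gene_gene(samples: list[PairSample], seed: int) -> SplitSpec:
    """Stratified 3:1:1 split preserving the class ratio in each part.

    Per class, 1/5 of the samples go to validation, 1/5 to test and the
    remainder to training, so each part's positive:negative ratio matches
    the global ratio to within one sample per class.
    """
    rng = np.random.default_rng(seed)
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for cls in (0, 1):
        idx = [i for i, s in enumerate(samples) if s.label == cls]
        if len(idx) < 5:
            raise ValueError(f"class {cls} has {len(idx)} samples; need >= 5")
        rng.shuffle(idx)
        n = len(idx)
        n_val, n_test = n // 5, n // 5
        val.extend(idx[:n_val])
        test.extend(idx[n_val : n_val + n_test])
        train.extend(idx[n_val + n_test :])
    return SplitSpec(sorted(train), sorted(val), sorted(test),
                     strategy="gene_gene_311", seed=seed)


def make_tf_folds(
    samples: list[PairSample],
    n_folds: int = 3,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[SplitSpec]:
    """TF-disjoint cross-validation folds.

    TF groups are sorted by descending sample count and assigned greedily to
    the currently smallest fold — deterministic and size-balancing.  Fold
    sizes are unequal in general because TFs regulate different numbers of
    genes.  Within each fold's complement, ``val_fraction`` of the samples
    (not of the TFs) form the validation set.
    """
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(s.tf_group, []).append(i)
    if len(groups) < n_folds:
        raise ValueError(f"{len(groups)} TF groups < {n_folds} folds")
    order = sorted(groups, key=lambda t: (-len(groups[t]), t))
    fold_tfs: list[list[str]] = [[] for _ in range(n_folds)]
    fold_sizes = [0] * n_folds
    for tf in order:
        j = int(np.argmin(fold_sizes))
        fold_tfs[j].append(tf)
        fold_sizes[j] += len(groups[tf])
    specs = []
    for fold_id in range(n_folds):
        test = sorted(i for tf in fold_tfs[fold_id] for i in groups[tf])
        rest = sorted(set(range(len(samples))) - set(test))
        rng = np.random.default_rng(np.random.SeedSequence([seed, fold_id]))
        rest = list(rest)
        rng.shuffle(rest)
        n_val = int(round(val_fraction * len(rest)))
        specs.append(
            SplitSpec(
                train=sorted(rest[n_val:]),
                val=sorted(rest[:n_val]),
                test=test,
                strategy="tf_3fold",
                fold_id=fold_id,
                seed=seed,
            )
        )
    return specs


def train_model(
    model: MotifTransformer,
    train_samples: list[PairSample],
    val_samples: list[PairSample],
    m: ExpressionMatrix,
    config: ModelConfig | None = None,
    log1p: bool = True,
    verbose: bool = False,
) -> tuple[MotifTransformer, list[dict]]:
    """Adam/BCE optimization; returns the best-validation-AUROC checkpoint.

    History rows carry epoch, train_loss, val_loss and val_auroc.  With
    ``epochs=0`` the initialized model and an empty history are returned.
    Fully reproducible from the config seed under single-threaded execution.
    """
    config = config or model.config
    X_tr, y_tr = encode_samples(train_samples, m, config.window, log1p=log1p)
    X_va, y_va = encode_samples(val_samples, m, config.window, log1p=log1p)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    history: list[dict] = []
    best_state, best_auroc = model.state_dict(), -np.inf
    n = len(train_samples)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss, grads, _ = model.loss_and_grads(X_tr[idx], y_tr[idx], training=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch offset {start} "
                    f"(samples {idx[:5].tolist()}...)"
                )
            model.adam_step(grads)
            losses.append(loss)
        val_prob = model.predict_proba(X_va)
        eps = 1e-12
        val_loss = float(
            -np.mean(y_va * np.log(val_prob + eps) + (1 - y_va) * np.log(1 - val_prob + eps))
        )
        if len(np.unique(y_va)) == 2:
            val_auroc = roc_pr_curves(y_va, val_prob).auroc
        else:
            val_auroc = float("nan")
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_auroc": val_auroc,
            }
        )
        msg = (
            f"epoch {epoch:3d}  train_loss {np.mean(losses):.4f}  "
            f"val_loss {val_loss:.4f}  val_auroc {val_auroc:.4f}"
        )
        logger.info(msg)
        if verbose:
            print(msg)
        if np.isfinite(val_auroc) and val_auroc > best_auroc:
            best_auroc = val_auroc
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history
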