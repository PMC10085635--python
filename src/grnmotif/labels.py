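"""Training-sample construction for the three classification tasks.

Three sample sets are supported, all anchored on transcription factors:

* ``gene_gene`` — unbalanced network reconstruction: every known (TF, target)
  edge is a positive and every other (TF, gene) pair a negative, preserving
  the natural class imbalance.
* ``interaction`` — balanced: each positive (a, b) is matched by one negative
  (a, c) with c drawn uniformly, without replacement per TF, from the genes a
  does not regulate.
* ``causality`` — balanced direction calling: each edge (a, b) yields
  (a, b) labelled 1 and the reversed (b, a) labelled 0.

Every sample carries a ``tf_group`` (the anchoring regulator) so that
TF-held-out cross-validation can keep all samples of one TF on one side of
the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io_data import EdgeList, ExpressionMatrix

Task = Literal["gene_gene", "interaction", "causality"]


class SampleError(ValueError):
    pass


@dataclass(frozen=True)
class PairSample:
    """One (regulator-slot gene, target-slot gene) training unit."""

    gene_a: str
    gene_b: str
    label: int
    task: Task
    tf_group: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise SampleError("label must be 0 or 1")
        if self.gene_a == self.gene_b:
            raise SampleError("self-pair sample")


def build_gene_gene_samples(
    net: EdgeList, m: ExpressionMatrix
) -> tuple[list[PairSample], dict]:
    """Unbalanced reconstruction samples over the full TF x gene grid.

    Positives are the resolvable edges; negatives are all remaining
    (TF, gene) pairs with a known-regulator TF.  No subsampling: the class
    imbalance of the network is preserved.  Returns the samples and a report
    with dropped-edge counts.
    """
    resolved, n_dropped = net.resolve(m)
    if not resolved.tf_ids:
        raise SampleError("no resolvable TFs in network")
    if not resolved.edges:
        raise SampleError("no resolvable positive edges in network")
    genes = [g.lower() for g in m.gene_ids]
    samples: list[PairSample] = []
    for tf in sorted(resolved.tf_ids):
        targets = resolved.targets_of(tf)
        for g in genes:
            if g == tf:
                continue
            label = 1 if g in targets else 0
            samples.append(PairSample(tf, g, label, "gene_gene", tf))
    report = {"n_dropped_edges": n_dropped, "n_tfs": len(resolved.tf_ids)}
    return samples, report


def build_interaction_samples(
    net: EdgeList, m: ExpressionMatrix, seed: int
) -> list[PairSample]:
    """Balanced interaction samples: one random non-target negative per edge.

    Negatives for one TF are drawn uniformly without replacement from the
    genes that TF does not regulate, so a negative gene is never repeated
    within a TF block.  Unmatched positives (a TF regulating nearly every
    gene) are dropped with a warning.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    resolved, _ = net.resolve(m)
    if not resolved.edges:
        raise SampleError("no resolvable positive edges in network")
    genes = [g.lower() for g in m.gene_ids]
    samples: list[PairSample] = []
    for tf in sorted(resolved.tf_ids):
        targets = sorted(resolved.targets_of(tf))
        if not targets:
            continue
        pool = [g for g in genes if g != tf and g not in set(targets)]
        if len(pool) < len(targets):
            warnings.warn(
                f"TF {tf}: only {len(pool)} candidate negatives for "
                f"{len(targets)} positives; dropping unmatched positives",
                stacklevel=2,
            )
            targets = targets[: len(pool)]
        negatives = rng.choice(pool, size=len(targets), replace=False)
        for b, c in zip(targets, negatives):
            samples.append(PairSample(tf, b, 1, "interaction", tf))
            samples.append(PairSample(tf, str(c), 0, "interaction", tf))
    if not samples:
        raise SampleError("no interaction samples could be built")
    return samples


def build_causality_samples(
    net: EdgeList, m: ExpressionMatrix, drop_bidirectional: bool = False
) -> list[PairSample]:
    """Balanced direction samples: (a,b) labelled 1, (b,a) labelled 0.

    Both directions of one edge carry ``tf_group = a`` (the true regulator),
    keeping the pair together under TF-held-out splitting.  An edge present
    in both directions makes the labels contradictory; it is an error unless
    ``drop_bidirectional`` removes both orientations.
    """
    resolved, _ = net.resolve(m)
    if not resolved.edges:
        raise SampleError("no resolvable positive edges in network")
    bidirectional = {(a, b) for a, b in resolved.edges if (b, a) in resolved.edges}
    edges = set(resolved.edges)
    if bidirectional:
        if not drop_bidirectional:
            raise SampleError(
                f"{len(bidirectional) // 2} bidirectional pair(s) present; "
                "pass drop_bidirectional=True to exclude them"
            )
        warnings.warn(
            f"dropping {len(bidirectional)} bidirectional edge orientation(s)",
            stacklevel=2,
        )
        edges -= bidirectional
    samples: list[PairSample] = []
    for a, b in sorted(edges):
        samples.append(PairSample(a, b, 1, "causality", a))
        samples.append(PairSample(b, a, 0, "causality", a))
    return samples


def save_samples(samples: list[PairSample], path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        [(s.gene_a, s.gene_b, s.label, s.task, s.tf_group) for s in samples],
        columns=["gene_a", "gene_b", "label", "task", "tf_group"],
    )
    df.to_csv(path, sep=delimiter, index=False)


def load_samples(path, delimiter: str = "\t") -> list[PairSample]:
    df = pd.read_csv(path, sep=delimiter)
    return [
        PairSample(r.gene_a, r.gene_b, int(r.label), r.task, r.tf_group)
        for r in df.itertuples()
    ]
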