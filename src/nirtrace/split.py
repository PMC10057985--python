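"""Monte-Carlo cross-validation (MCCV) train/test partitioning.

MCCV repeatedly draws a random train/test partition without replacement —
70% train / 30% test by default — and reports metrics averaged over the
repeats.  Splits are stratified by class by default so the 2127:1530-style
class imbalance of origin datasets is preserved in every partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StratificationError


@dataclass(frozen=True)
class MCCVPlan:
    n_samples: int
    train_fraction: float = 0.7
    n_repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")
        if self.n_samples < 2:
            raise ParameterError("need at least 2 samples to split")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mccv_splits(labels, plan: MCCVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``plan.n_repeats`` random (train, test) index pairs.

    Train size is round(train_fraction · N) overall, or per class when
    stratified; partitions are disjoint and exhaustive, and the sequence is
    fully reproducible from ``plan.seed``.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != plan.n_samples:
        raise ParameterError("labels length must equal plan.n_samples")
    rng = np.random.default_rng(plan.seed)
    classes = sorted(set(labels.tolist()))
    if plan.stratified:
        for c in classes:
            if int(np.sum(labels == c)) < 2:
                raise StratificationError(
                    f"class {c!r} has fewer than 2 samples; cannot stratify")

    out = []
    for _ in range(plan.n_repeats):
        if plan.stratified:
            train_parts, test_parts = [], []
            for c in classes:
                idx = np.flatnonzero(labels == c)
                perm = rng.permutation(idx)
                n_train = _round_half_up(plan.train_fraction * idx.size)
                n_train = min(max(n_train, 1), idx.size - 1)
                train_parts.append(perm[:n_train])
                test_parts.append(perm[n_train:])
            train = np.sort(np.concatenate(train_parts))
            test = np.sort(np.concatenate(test_parts))
        else:
            perm = rng.permutation(plan.n_samples)
            n_train = _round_half_up(plan.train_fraction * plan.n_samples)
            n_train = min(max(n_train, 1), plan.n_samples - 1)
            train = np.sort(perm[:n_train])
            test = np.sort(perm[n_train:])
        out.append((train, test))
    return out
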