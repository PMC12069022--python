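"""Subject-level fold machinery: nested cross-validation and final splits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldPlan", "make_fold_plan", "make_final_split"]


def _chunk(indices: np.ndarray, k: int):
    """Split an index array into k contiguous chunks with sizes within 1."""
    return [c.tolist() for c in np.array_split(indices, k)]


@dataclass
class FoldPlan:
    """Nested cross-validation plan.

    ``outer_folds[i] = (trainval, test)``; ``inner_folds[i]`` holds, for
    outer fold i, a list of (train, val) partitions of ``trainval``.
    """

    outer_folds: list
    inner_folds: list
    n_subjects: int


def make_fold_plan(
    n_subjects: int, n_outer: int = 3, n_inner: int = 5, seed: int = 0
) -> FoldPlan:
    """Deterministic n_outer x n_inner nested cross-validation split.

    Outer test sets partition all subjects; within each outer fold the
    inner validation sets partition the outer train+val set, equal-sized
    within one subject.
    """
    if n_subjects < n_outer * n_inner:
        raise ValueError(
            f"need at least {n_outer * n_inner} subjects for a "
            f"{n_outer}x{n_inner} nested CV, got {n_subjects}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    test_sets = _chunk(perm, n_outer)
    outer_folds, inner_folds = [], []
    for i in range(n_outer):
        test = sorted(test_sets[i])
        trainval = sorted(set(range(n_subjects)) - set(test))
        inner_perm = rng.permutation(trainval)
        val_sets = _chunk(inner_perm, n_inner)
        inner = []
        for v in val_sets:
            val = sorted(v)
            train = sorted(set(trainval) - set(val))
            inner.append((train, val))
        outer_folds.append((trainval, test))
        inner_folds.append(inner)
    return FoldPlan(outer_folds=outer_folds, inner_folds=inner_folds, n_subjects=n_subjects)


def make_final_split(n_subjects: int, k: int = 5, seed: int = 0):
    """k (train, val) partitions with disjoint equal-sized validation sets.

    Each member net trains on the complement of its validation subset,
    so the k validation sets cover all subjects exactly once.
    """
    if n_subjects < k:
        raise ValueError(f"need at least {k} subjects, got {n_subjects}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    val_sets = _chunk(perm, k)
    splits = []
    for v in val_sets:
        val = sorted(v)
        train = sorted(set(range(n_subjects)) - set(val))
        splits.append((train, val))
    return splits
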