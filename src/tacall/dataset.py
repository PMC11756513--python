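"""Feature-matrix assembly, label joining, and train/test splitting.

The calling models consume a fixed-width matrix with one row per reaction and
one column per cycle of normalized fluorescence.  A duplex well contributes
one row per dye.  The train/test split is a simple seeded random partition of
reactions with an exact floor rule: ``n_train = floor(fraction * N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .curve_io import ReactionLabel
from .errors import AlignmentError, TacallError
from .normalization import NormalizedTrace

__all__ = ["ReactionDataset", "assemble", "split", "amplified_subset"]


@dataclass(eq=False)
class ReactionDataset:
    """Aligned features and gold-standard labels for N reactions.

    ``features`` is N x C normalized fluorescence; ``ct`` holds NaN for
    non-amplified reactions.
    """

    features: np.ndarray
    ids: list[str]
    dyes: list[str]
    amplified: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.amplified = np.asarray(self.amplified, dtype=bool)
        self.ct = np.asarray(self.ct, dtype=float)
        n = self.features.shape[0]
        if not (len(self.ids) == len(self.dyes) == len(self.amplified) == len(self.ct) == n):
            raise TacallError("features, ids, dyes, amplified, and ct must align")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def cycles(self) -> int:
        return self.features.shape[1]

    def take(self, indices: Sequence[int] | np.ndarray) -> "ReactionDataset":
        """Row subset by positional indices, preserving order."""
        idx = np.asarray(indices, dtype=int)
        return ReactionDataset(
            features=self.features[idx],
            ids=[self.ids[i] for i in idx],
            dyes=[self.dyes[i] for i in idx],
            amplified=self.amplified[idx],
            ct=self.ct[idx],
        )

    def labels(self) -> list[ReactionLabel]:
        return [
            ReactionLabel(rid, bool(a), float(c) if a else None)
            for rid, a, c in zip(self.ids, self.amplified, self.ct)
        ]


def assemble(
    traces: Sequence[NormalizedTrace], labels: Sequence[ReactionLabel]
) -> ReactionDataset:
    """Join normalized traces with labels by reaction_id into a dataset.

    Rows follow the input trace order.  Unmatched ids in either direction and
    mixed cycle counts raise :class:`AlignmentError`.
    """
    by_id = {}
    for lab in labels:
        if lab.reaction_id in by_id:
            raise AlignmentError(f"duplicate label for reaction {lab.reaction_id!r}")
        by_id[lab.reaction_id] = lab

    seen = set()
    for t in traces:
        if t.reaction_id in seen:
            raise AlignmentError(f"duplicate trace for reaction {t.reaction_id!r}")
        seen.add(t.reaction_id)

    missing_labels = [t.reaction_id for t in traces if t.reaction_id not in by_id]
    if missing_labels:
        raise AlignmentError(f"traces without labels: {missing_labels}")
    extra_labels = sorted(set(by_id) - seen)
    if extra_labels:
        raise AlignmentError(f"labels without traces: {extra_labels}")

    cycle_counts = {t.cycles for t in traces}
    if len(cycle_counts) > 1:
        raise AlignmentError(f"mixed cycle counts in traces: {sorted(cycle_counts)}")
    if not traces:
        raise AlignmentError("cannot assemble an empty dataset")

    feats = np.vstack([t.values for t in traces])
    amp = np.array([by_id[t.reaction_id].amplified for t in traces], dtype=bool)
    ct = np.array(
        [
            by_id[t.reaction_id].ct if by_id[t.reaction_id].amplified else np.nan
            for t in traces
        ],
        dtype=float,
    )
    return ReactionDataset(
        features=feats,
        ids=[t.reaction_id for t in traces],
        dyes=[t.dye for t in traces],
        amplified=amp,
        ct=ct,
    )


def split(
    dataset: ReactionDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    groups: Sequence[str] | None = None,
) -> tuple[ReactionDataset, ReactionDataset]:
    """Seeded random partition into train and test sets.

    The train size is exactly ``floor(train_fraction * N)``.  With ``groups``
    (e.g. well ids, to avoid leakage between duplexed reactions), whole groups
    are assigned to the training side until the target size would be
    exceeded, so the realized train size is the closest achievable not above
    the floor target.
    """
    if not 0.0 < train_fraction < 1.0:
        raise TacallError("train_fraction must lie strictly in (0, 1)")
    if dataset.n < 2:
        raise TacallError("need at least 2 reactions to split")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(train_fraction * dataset.n))

    if groups is None:
        perm = rng.permutation(dataset.n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        if len(groups) != dataset.n:
            raise TacallError("groups must align with dataset rows")
        uniq = list(dict.fromkeys(groups))
        order = rng.permutation(len(uniq))
        members: dict[str, list[int]] = {}
        for i, g in enumerate(groups):
            members.setdefault(g, []).append(i)
        train_idx_list: list[int] = []
        test_idx_list: list[int] = []
        for j in order:
            grp = members[uniq[j]]
            if len(train_idx_list) + len(grp) <= n_train:
                train_idx_list.extend(grp)
            else:
                test_idx_list.extend(grp)
        train_idx = np.array(sorted(train_idx_list), dtype=int)
        test_idx = np.array(sorted(test_idx_list), dtype=int)

    return dataset.take(train_idx), dataset.take(test_idx)


def amplified_subset(dataset: ReactionDataset) -> ReactionDataset:
    """Rows whose gold-standard label is amplified (Ct present on each).

    Used to train the conditional Ct regressor.  An empty result is allowed
    but raises a warning.
    """
    idx = np.flatnonzero(dataset.amplified)
    if idx.size == 0:
        warnings.warn("amplified_subset: no amplified reactions in dataset", stacklevel=2)
    return dataset.take(idx)
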