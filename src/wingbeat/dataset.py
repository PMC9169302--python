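"""Corpus-level protocol: validity filtering, class balancing, splits, folds.

The study protocol is: drop recordings flagged invalid on review, balance
classes by random under-sampling, hold out a random 25% test set, and
build four equal cross-validation folds from the remaining 75%. Splits
and folds here are stratified by class label so the balanced design
survives the split; a ``stratify=False`` flag restores the purely random
draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from wingbeat.sensor_sim import WingbeatRecording

TASKS = ("genus", "sex_aedes", "sex_culex")

#: Class column and genus restriction for each classification task.
TASK_DEFS: Mapping[str, tuple[str, str | None]] = {
    "genus": ("genus", None),
    "sex_aedes": ("sex", "Aedes"),
    "sex_culex": ("sex", "Culex"),
}


@dataclass
class LabeledCorpus:
    """A collection of labelled wingbeat recordings."""

    recordings: list[WingbeatRecording]
    class_column: str = "genus"
    task: str | None = None

    def __post_init__(self) -> None:
        if self.task is not None:
            column, genus = TASK_DEFS[self.task]
            self.class_column = column
            if genus is not None:
                bad = [r for r in self.recordings if r.genus != genus]
                if bad:
                    raise ValueError(
                        f"task {self.task!r} requires all recordings of genus {genus}"
                    )

    def __len__(self) -> int:
        return len(self.recordings)

    def labels(self, column: str | None = None) -> np.ndarray:
        column = column or self.class_column
        return np.array([getattr(r, column) for r in self.recordings])

    def subset(self, indices: Iterable[int]) -> "LabeledCorpus":
        recs = [self.recordings[i] for i in indices]
        return LabeledCorpus(recordings=recs, class_column=self.class_column,
                             task=self.task)

    def class_counts(self, column: str | None = None) -> dict[str, int]:
        labels, counts = np.unique(self.labels(column), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def for_task(self, task: str) -> "LabeledCorpus":
        """Restrict to the recordings of a classification task.

        ``genus`` keeps everything; the sex tasks keep one genus and switch
        the class column to ``sex``.
        """
        column, genus = TASK_DEFS[task]
        recs = [r for r in self.recordings if genus is None or r.genus == genus]
        return LabeledCorpus(recordings=recs, class_column=column, task=task)


@dataclass
class Split:
    """Train/test partition of a corpus, with optional CV fold ids.

    ``fold_assignment`` aligns with ``train_indices`` and holds fold ids
    1..k once :func:`make_folds` has run.
    """

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    fold_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test sets overlap")

    @property
    def n(self) -> int:
        return len(self.train_indices) + len(self.test_indices)

    def fold_train_val(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Corpus indices for one CV round: (train-on, validate-on)."""
        if self.fold_assignment is None:
            raise ValueError("folds have not been assigned; call make_folds first")
        mask = self.fold_assignment == fold
        return self.train_indices[~mask], self.train_indices[mask]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "train_indices": self.train_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "fold_assignment": None if self.fold_assignment is None
            else self.fold_assignment.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Split":
        payload = json.loads(Path(path).read_text())
        folds = payload["fold_assignment"]
        return cls(
            train_indices=np.array(payload["train_indices"], dtype=int),
            test_indices=np.array(payload["test_indices"], dtype=int),
            seed=payload["seed"],
            fold_assignment=None if folds is None else np.array(folds, dtype=int),
        )


def filter_valid(corpus: LabeledCorpus) -> tuple[LabeledCorpus, int]:
    """Drop recordings flagged invalid; return the kept corpus and the count removed."""
    kept = [r for r in corpus.recordings if r.valid]
    excluded = len(corpus) - len(kept)
    return (
        LabeledCorpus(recordings=kept, class_column=corpus.class_column, task=corpus.task),
        excluded,
    )


def _stratum_keys(
    corpus: LabeledCorpus, strata: Sequence[str] | Callable[[WingbeatRecording], tuple]
) -> list[tuple]:
    if callable(strata):
        return [strata(r) for r in corpus.recordings]
    return [tuple(getattr(r, col) for col in strata) for r in corpus.recordings]


def balance_by_strata(
    corpus: LabeledCorpus,
    strata: Sequence[str] | Callable[[WingbeatRecording], tuple] = ("species", "sex"),
    per_stratum_quota: int | str | Mapping[tuple, int] = "min",
    seed: int = 0,
) -> LabeledCorpus:
    """Random under-sampling to equal (or quota-specified) stratum sizes.

    ``strata`` names recording attributes (default species x sex) or is a
    key function. The quota is ``"min"`` (smallest stratum size), a single
    integer for every stratum, or a mapping from stratum key to count.
    Sampling is without replacement and seeded; the output preserves the
    original recording order.
    """
    keys = _stratum_keys(corpus, strata)
    return corpus.subset(balance_indices(keys, per_stratum_quota, seed))


def balance_indices(
    keys: Sequence[tuple],
    per_stratum_quota: int | str | Mapping[tuple, int] = "min",
    seed: int = 0,
) -> list[int]:
    """Index-level under-sampling: one stratum key per row, returns kept rows."""
    by_stratum: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        by_stratum.setdefault(key, []).append(i)
    if not by_stratum:
        raise ValueError("every stratum must be non-empty")

    min_size = min(len(v) for v in by_stratum.values())
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for key in sorted(by_stratum):
        idx = by_stratum[key]
        if per_stratum_quota == "min":
            quota = min_size
        elif isinstance(per_stratum_quota, Mapping):
            quota = per_stratum_quota[key]
        else:
            quota = int(per_stratum_quota)
        if quota > len(idx):
            raise ValueError(
                f"quota {quota} exceeds stratum {key!r} size {len(idx)}"
            )
        chosen.extend(rng.choice(idx, size=quota, replace=False).tolist())
    chosen.sort()
    return chosen


def _allocate(counts: Sequence[int], total_target: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total_target`` across groups."""
    raw = [c * w for c, w in zip(counts, weights)]
    floors = [int(np.floor(r)) for r in raw]
    short = total_target - sum(floors)
    order = np.argsort([-(r - f) for r, f in zip(raw, floors)], kind="stable")
    for j in order[:short]:
        floors[j] += 1
    return floors


def train_test_split(
    corpus: LabeledCorpus,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify: bool = True,
) -> Split:
    """Random train/test partition: ``round(train_fraction * n)`` training.

    Stratified by the corpus class column by default, so each class keeps
    the same train share within one recording; set ``stratify=False`` for
    the purely random draw.
    """
    return split_by_labels(corpus.labels(), train_fraction, seed, stratify)


def split_by_labels(
    labels: np.ndarray,
    train_fraction: float = 0.75,
    seed: int = 0,
    stratify: bool = True,
) -> Split:
    """Label-array form of :func:`train_test_split`."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("corpus must contain at least 4 recordings")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))

    if not stratify:
        perm = rng.permutation(n)
        return Split(train_indices=np.sort(perm[:n_train]),
                     test_indices=np.sort(perm[n_train:]), seed=seed)

    classes = sorted(set(labels.tolist()))
    per_class = {c: np.flatnonzero(labels == c) for c in classes}
    counts = [len(per_class[c]) for c in classes]
    train_counts = _allocate(counts, n_train, [train_fraction] * len(classes))
    train_idx: list[int] = []
    for c, t_c in zip(classes, train_counts):
        idx = per_class[c].copy()
        rng.shuffle(idx)
        train_idx.extend(idx[:t_c].tolist())
    train = np.sort(np.array(train_idx, dtype=int))
    test = np.setdiff1d(np.arange(n), train)
    return Split(train_indices=train, test_indices=test, seed=seed)


def make_folds(
    split: Split,
    labels: np.ndarray,
    k: int = 4,
    seed: int | None = None,
) -> Split:
    """Assign the training set to ``k`` equal cross-validation folds.

    ``labels`` are the class labels of the whole corpus (indexed by the
    split's corpus indices). Folds are stratified by class; when sizes do
    not divide evenly the remainder is spread one recording per fold, so
    fold sizes differ by at most one. Returns a new Split carrying fold
    ids 1..k aligned with ``train_indices``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    seed = split.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train = split.train_indices
    assignment = np.zeros(len(train), dtype=int)
    fold_loads = np.zeros(k, dtype=int)
    classes = sorted(set(labels[train].tolist()))
    for c in classes:
        pos = np.flatnonzero(labels[train] == c)
        rng.shuffle(pos)
        base, rem = divmod(len(pos), k)
        # Give the remainder to the currently least-loaded folds.
        order = np.argsort(fold_loads, kind="stable")
        sizes = np.full(k, base, dtype=int)
        sizes[order[:rem]] += 1
        cursor = 0
        for fold_id in range(k):
            take = sizes[fold_id]
            assignment[pos[cursor : cursor + take]] = fold_id + 1
            fold_loads[fold_id] += take
            cursor += take
    return Split(
        train_indices=train.copy(),
        test_indices=split.test_indices.copy(),
        seed=split.seed,
        fold_assignment=assignment,
    )
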