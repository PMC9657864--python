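"""Windowing and splitting of feature streams.

The classifier consumes fixed-length windows: 18 consecutive frames (about
one second at the ~18 Hz frame rate) by m features. Windows never overlap —
the monitor is meant to run continuously, each second of motion judged once —
and a trailing remainder shorter than the window is dropped.

Class balance is restored before windowing by *down-sampling only*: rows of
the majority class are removed (never synthesized) by truncating whole
contiguous tail blocks of majority-class trials, so every surviving row still
sits in an unbroken time series.

Splitting preserves temporal order by default (no shuffling): the first
``train_fraction`` of windows form the train+validation block, whose tail is
the validation set; the remainder is the test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .features import FeatureRow, FeatureSetSpec, resolve_feature_set, select_features

DEFAULT_WINDOW_LENGTH = 18


@dataclass(frozen=True, slots=True)
class FeatureWindow:
    """One classifier input: a (window_length x m) block of consecutive rows."""

    matrix: np.ndarray
    label: int
    origin: tuple[str, str, int]  # (subject_id, trial_id, start row index in trial)

    def __post_init__(self) -> None:
        if not np.isfinite(self.matrix).all():
            raise DataError(f"non-finite values in window from {self.origin}")


@dataclass(frozen=True, slots=True)
class SplitSpec:
    train_fraction: float = 0.69
    val_fraction_of_train: float = 0.20
    shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_fraction", "val_fraction_of_train"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _trial_runs(rows: Sequence[FeatureRow]) -> list[tuple[tuple[str, str], list[int]]]:
    """Contiguous runs of row indices per (subject, trial), in encounter order."""
    runs: list[tuple[tuple[str, str], list[int]]] = []
    for i, r in enumerate(rows):
        key = (r.subject_id, r.trial_id)
        if runs and runs[-1][0] == key:
            runs[-1][1].append(i)
        else:
            runs.append((key, [i]))
    return runs


def balance_classes(
    rows: Sequence[FeatureRow],
    seed: int,
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> list[FeatureRow]:
    """Down-sample the majority class until counts are equal within one window.

    Whole tail blocks of majority-class trials are removed (seeded choice of
    trial each round) so no trial acquires an internal gap. Trials whose tail
    row belongs to the minority class are never touched.
    """
    rows = list(rows)
    counts = {0: 0, 1: 0}
    for r in rows:
        counts[r.label] += 1
    if counts[0] == 0 or counts[1] == 0:
        raise DataError("both classes must be present before balancing")
    majority = 0 if counts[0] > counts[1] else 1
    excess = counts[majority] - counts[1 - majority]
    if excess <= window_length:
        return rows

    rng = np.random.default_rng(seed)
    drop: set[int] = set()
    # trailing majority-class run length per trial, shrinking as we cut
    runs = _trial_runs(rows)
    tails: dict[tuple[str, str], list[int]] = {}
    for key, idx in runs:
        # contiguous trailing majority-class run of this trial, tail-first
        run = []
        expect = idx[-1]
        for i in idx[::-1]:
            if rows[i].label != majority or i != expect:
                break
            run.append(i)
            expect = i - 1
        if run:
            tails[key] = run  # run is ordered tail-first
    while excess > window_length and tails:
        keys = sorted(tails)  # deterministic ordering for the rng draw
        key = keys[rng.integers(len(keys))]
        run = tails.pop(key)
        take = min(excess, len(run))
        drop.update(run[:take])
        excess -= take
    return [r for i, r in enumerate(rows) if i not in drop]


def make_windows(
    rows: Sequence[FeatureRow],
    spec: FeatureSetSpec | str,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    label_rule: str = "any",
) -> list[FeatureWindow]:
    """Cut the feature stream into non-overlapping windows, per trial.

    A window is labeled ``fall`` if *any* of its frames is a fall frame
    (``label_rule="any"``, the default — the system exists to raise alarms,
    so a window that sees any part of a fall counts as one) or by majority
    vote (``label_rule="majority"``).
    """
    if window_length < 1:
        raise ConfigurationError("window_length must be >= 1")
    if label_rule not in {"any", "majority"}:
        raise ConfigurationError(f"unknown label_rule {label_rule!r}")
    spec = resolve_feature_set(spec)
    windows: list[FeatureWindow] = []
    for key, idx in _trial_runs(rows):
        n_full = len(idx) // window_length
        for w in range(n_full):
            block = [rows[i] for i in idx[w * window_length:(w + 1) * window_length]]
            labels = [r.label for r in block]
            if label_rule == "any":
                label = int(any(labels))
            else:
                label = int(sum(labels) * 2 >= len(labels))
            windows.append(
                FeatureWindow(
                    matrix=select_features(block, spec),
                    label=label,
                    origin=(key[0], key[1], w * window_length),
                )
            )
    return windows


def split_windows(
    windows: Sequence[FeatureWindow],
    spec: SplitSpec = SplitSpec(),
    train_count: int | None = None,
) -> tuple[list[FeatureWindow], list[FeatureWindow], list[FeatureWindow]]:
    """Partition windows into (train, validation, test).

    With ``shuffle=False`` the split is purely positional: the first
    ``round(train_fraction * n)`` windows are train+validation (the last
    ``val_fraction_of_train`` of that block is validation) and the rest test.
    ``train_count`` overrides the fraction with an absolute train+validation
    pack count, so either a fraction-based or an absolute accounting of the
    same corpus can be reproduced. Fractional sizes round half up.
    """
    windows = list(windows)
    n = len(windows)
    if n < 3:
        raise DataError(f"need at least 3 windows to split, got {n}")
    if spec.shuffle:
        order = np.random.default_rng(spec.seed).permutation(n)
        windows = [windows[i] for i in order]
    n_trainval = train_count if train_count is not None else _round_half_up(
        spec.train_fraction * n
    )
    if not 0 < n_trainval < n:
        raise ConfigurationError(
            f"train+validation count {n_trainval} leaves an empty split (n={n})"
        )
    n_val = _round_half_up(spec.val_fraction_of_train * n_trainval)
    n_train = n_trainval - n_val
    if n_train == 0 or n_val == 0:
        raise ConfigurationError(
            f"split produced an empty train or validation set "
            f"(train={n_train}, val={n_val})"
        )
    return (
        windows[:n_train],
        windows[n_train:n_trainval],
        windows[n_trainval:],
    )


def to_model_tensors(
    windows: Sequence[FeatureWindow],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into an (n, window_length, m) array and an (n,) label
    vector (fall=1), preserving list order."""
    if not windows:
        raise DataError("no windows to stack")
    shapes = {w.matrix.shape for w in windows}
    if len(shapes) > 1:
        raise DataError(f"heterogeneous window shapes: {sorted(shapes)}")
    X = np.stack([w.matrix for w in windows]).astype(float)
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


def save_windows(
    windows: Sequence[FeatureWindow],
    out_dir: str | Path,
    feature_set: str,
    window_length: int,
    split: SplitSpec | None = None,
    seed: int | None = None,
) -> Path:
    """Serialize a windowed dataset: inputs.npy + labels.npy + manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, y = to_model_tensors(windows)
    np.save(out / "inputs.npy", X)
    np.save(out / "labels.npy", y)
    manifest = {
        "window_length": window_length,
        "m": int(X.shape[2]),
        "feature_set": feature_set,
        "n_windows": int(X.shape[0]),
        "split": None if split is None else {
            "train_fraction": split.train_fraction,
            "val_fraction_of_train": split.val_fraction_of_train,
            "shuffle": split.shuffle,
            "seed": split.seed,
        },
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
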