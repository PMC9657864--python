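"""Keypoint time-series I/O.

The package consumes the output of a pose-extraction step: per video frame,
the image-space coordinates of three anatomical key points — nose (N), left
shoulder (LSh) and left hip (LH) — in a coordinate frame whose origin sits at
the outer left corner of the image with the positive y-axis pointing *down*
toward the floor. Streams are stored as plain CSV, one row per frame, grouped
into trials (one recording of one activity by one subject).

A frame may be flagged ``excluded``: either the pose extractor could not read
all three key points, or the frame was annotated as post-impact (the subject
has already hit the floor). Excluded frames are retained on disk so the raw
record is preserved; :func:`apply_frame_filters` removes them before feature
computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, DataError, FormatError

#: Canonical CSV column order for keypoint streams.
COLUMNS = [
    "t",
    "subject_id",
    "trial_id",
    "activity_id",
    "excluded",
    "N_x",
    "N_y",
    "N_z",
    "LSh_x",
    "LSh_y",
    "LSh_z",
    "LH_x",
    "LH_y",
    "LH_z",
]

_COORD_COLUMNS = COLUMNS[5:]

#: Default activity-code semantics (UP-Fall convention): codes 1-5 are fall
#: activities, 6-11 are activities of daily living.
DEFAULT_ACTIVITY_MAP: dict[int, str] = {
    1: "fall",  # falling forward using hands
    2: "fall",  # falling forward using knees
    3: "fall",  # falling backward
    4: "fall",  # falling sideward
    5: "fall",  # falling while sitting in an empty chair
    6: "not_fall",  # walking
    7: "not_fall",  # standing
    8: "not_fall",  # sitting
    9: "not_fall",  # picking up an object
    10: "not_fall",  # jumping
    11: "not_fall",  # lying down
}


@dataclass(frozen=True, slots=True)
class KeypointFrame:
    """One time-stamped observation of the three tracked key points."""

    t: float
    subject_id: str
    trial_id: str
    activity_id: int
    N_x: float = math.nan
    N_y: float = math.nan
    N_z: float = math.nan
    LSh_x: float = math.nan
    LSh_y: float = math.nan
    LSh_z: float = math.nan
    LH_x: float = math.nan
    LH_y: float = math.nan
    LH_z: float = math.nan
    excluded: bool = False

    def coords(self) -> tuple[float, ...]:
        return (
            self.N_x, self.N_y, self.N_z,
            self.LSh_x, self.LSh_y, self.LSh_z,
            self.LH_x, self.LH_y, self.LH_z,
        )


@dataclass(slots=True)
class KeypointSequence:
    """All frames of one (subject, trial), ordered by time."""

    frames: list[KeypointFrame]
    nominal_fps: float = 18.0

    def __post_init__(self) -> None:
        if self.nominal_fps <= 0:
            raise ConfigurationError(
                f"nominal_fps must be positive, got {self.nominal_fps}"
            )
        if self.frames:
            key = (self.frames[0].subject_id, self.frames[0].trial_id)
            for f in self.frames:
                if (f.subject_id, f.trial_id) != key:
                    raise DataError(
                        f"frames mix trials: {key} vs {(f.subject_id, f.trial_id)}"
                    )

    @property
    def subject_id(self) -> str:
        return self.frames[0].subject_id

    @property
    def trial_id(self) -> str:
        return self.frames[0].trial_id

    def __len__(self) -> int:
        return len(self.frames)


def read_keypoints(path: str | Path) -> list[KeypointSequence]:
    """Read a keypoint CSV into one :class:`KeypointSequence` per (subject, trial).

    Rows whose coordinates cannot all be read as finite numbers are kept with
    ``excluded=True`` rather than dropped, matching the convention that the raw
    stream is preserved and filtering is a separate, explicit step.

    Raises
    ------
    FormatError
        If a required column is missing (the message names the column).
    DataError
        If timestamps are not strictly increasing within a trial.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    for col in COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")

    sequences: list[KeypointSequence] = []
    # groupby(sort=False) preserves first-appearance order of trials
    for (subject, trial), g in df.groupby(["subject_id", "trial_id"], sort=False):
        g = g.sort_values("t", kind="stable")
        t = g["t"].to_numpy(dtype=float)
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise DataError(
                f"non-monotone timestamps in trial ({subject!r}, {trial!r})"
            )
        frames = []
        for row in g.itertuples(index=False):
            coords = {}
            unreadable = False
            for col in _COORD_COLUMNS:
                v = getattr(row, col)
                try:
                    v = float(v)
                except (TypeError, ValueError):
                    v = math.nan
                if not math.isfinite(v):
                    unreadable = True
                coords[col] = v
            excluded = _as_bool(row.excluded) or unreadable
            frames.append(
                KeypointFrame(
                    t=float(row.t),
                    subject_id=str(subject),
                    trial_id=str(trial),
                    activity_id=int(row.activity_id),
                    excluded=excluded,
                    **coords,
                )
            )
        sequences.append(KeypointSequence(frames=frames))
    return sequences


def _as_bool(v: object) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "t", "yes"}
    if isinstance(v, float) and math.isnan(v):
        return False
    return bool(v)


def write_keypoints(sequences: Iterable[KeypointSequence], path: str | Path) -> Path:
    """Write sequences to CSV in the canonical column order.

    Floats are written with 9 significant digits so a read/write round trip
    preserves numeric content to well beyond measurement precision.
    """
    sequences = list(sequences)
    if not sequences:
        raise DataError("no sequences to write")
    for seq in sequences:
        if not seq.frames:
            raise DataError("sequence with no frames cannot be written")
    records = [
        {col: getattr(f, col) for col in COLUMNS}
        for seq in sequences
        for f in seq.frames
    ]
    df = pd.DataFrame.from_records(records, columns=COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def apply_frame_filters(seq: KeypointSequence) -> KeypointSequence:
    """Drop unusable frames from a trial.

    The retained stream is everything strictly before the first excluded
    frame. The flag marks either an unreadable frame or the impact annotation;
    in both cases every later frame is discarded: once a fall has reached the
    floor the trial is over, and a break in the keypoint stream would corrupt
    the finite-difference features. Idempotent; may return an empty sequence.
    """
    kept: list[KeypointFrame] = []
    for f in seq.frames:
        if f.excluded:
            break
        kept.append(f)
    return KeypointSequence(frames=kept, nominal_fps=seq.nominal_fps)


def load_activity_map(path: str | Path | None = None) -> dict[int, str]:
    """Load an activity_id -> {"fall", "not_fall"} mapping from YAML/JSON.

    With no path, returns the default 5-fall / 6-ADL convention.
    """
    if path is None:
        return dict(DEFAULT_ACTIVITY_MAP)
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out: dict[int, str] = {}
    for k, v in raw.items():
        v = str(v)
        if v not in {"fall", "not_fall"}:
            raise FormatError(f"activity map value must be fall/not_fall, got {v!r}")
        out[int(k)] = v
    return out


def binary_labels(activity_map: Mapping[int, str]) -> dict[int, int]:
    """Collapse an activity map to integer labels (fall=1, not_fall=0)."""
    return {k: 1 if v == "fall" else 0 for k, v in activity_map.items()}
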