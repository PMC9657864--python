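"""Per-frame kinematic features.

Three quantities are derived from the tracked key points, all in the image
coordinate frame (origin at the outer left corner, y down toward the floor):

* ``A_i = arctan(y_i / x_i)`` — the angle (radians) between the line joining
  key point *i* to the origin and the x-axis, for i in {N, LSh, LH};
* ``dw_i = ΔA_i / Δt`` — the angular rate (rad/s) of that line between
  consecutive frames, with the first frame's rate set to 0 by convention;
* ``R = N_y / LH_y`` — the nose-to-hip height ratio. Because y grows toward
  the floor, R < 1 while the nose is above the hip and crosses 1 exactly when
  the head reaches hip height — the kinematic signature of a body going down.

The three model variants consume fixed subsets of these:

* ``4p``: N_x, N_y, dw_N, R
* ``5p``: N_x, N_y, dw_N, dw_LSh, dw_LH
* ``6p``: N_x, N_y, dw_N, dw_LSh, dw_LH, R
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError
from .io_keypoints import KeypointSequence

logger = logging.getLogger(__name__)

#: Below this |x| the angle is reported as the limit value sign(y)*pi/2.
ANGLE_X_EPSILON = 1e-9


@dataclass(frozen=True, slots=True)
class FeatureRow:
    """Derived kinematic quantities for one frame."""

    t: float
    subject_id: str
    trial_id: str
    label: int  # fall=1, not_fall=0
    N_x: float
    N_y: float
    A_N: float
    A_LSh: float
    A_LH: float
    dw_N: float
    dw_LSh: float
    dw_LH: float
    R: float


@dataclass(frozen=True, slots=True)
class FeatureSetSpec:
    name: str
    columns: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.columns)


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    "4p": FeatureSetSpec("4p", ("N_x", "N_y", "dw_N", "R")),
    "5p": FeatureSetSpec("5p", ("N_x", "N_y", "dw_N", "dw_LSh", "dw_LH")),
    "6p": FeatureSetSpec("6p", ("N_x", "N_y", "dw_N", "dw_LSh", "dw_LH", "R")),
}

#: Columns of the feature-table CSV (superset of all model inputs).
FEATURE_COLUMNS = [
    "t", "subject_id", "trial_id", "label",
    "N_x", "N_y", "dw_N", "dw_LSh", "dw_LH", "R",
]


def angle_to_origin(x: float, y: float, eps: float = ANGLE_X_EPSILON) -> float:
    """Angle between the keypoint-to-origin line and the x-axis, in radians.

    Implements arctan(y/x) as printed, with a guard at x -> 0 where the limit
    value sign(y)*pi/2 is returned and a warning logged. Image coordinates are
    positive in the stated frame, so the guard is a degenerate-input safety
    net rather than an expected path.
    """
    if abs(x) < eps:
        logger.warning("angle_to_origin: |x|=%g below epsilon, returning limit", x)
        return math.copysign(math.pi / 2, y)
    return math.atan(y / x)


def angular_rate(
    angles: Sequence[float], times: Sequence[float]
) -> np.ndarray:
    """Per-frame finite-difference angular rate, rad/s.

    Element k (k >= 1) is (angles[k] - angles[k-1]) / (times[k] - times[k-1]);
    element 0 is 0 by convention so the output aligns row-for-row with the
    input frames.
    """
    a = np.asarray(angles, dtype=float)
    t = np.asarray(times, dtype=float)
    if a.shape != t.shape or a.ndim != 1 or a.size < 1:
        raise DataError("angles and times must be equal-length 1-D, length >= 1")
    if a.size > 1 and not (np.diff(t) > 0).all():
        raise DataError("times must be strictly increasing")
    out = np.zeros_like(a)
    if a.size > 1:
        out[1:] = np.diff(a) / np.diff(t)
    return out


def nose_hip_ratio(n_y: float, lh_y: float) -> float:
    """Ratio of nose y to left-hip y. With y pointing down, values above 1
    mean the head is at or below hip height."""
    if lh_y == 0:
        raise DataError("nose_hip_ratio undefined: LH_y is zero")
    return n_y / lh_y


def compute_features(
    seq: KeypointSequence, labels: Mapping[int, int]
) -> list[FeatureRow]:
    """Compute one :class:`FeatureRow` per frame of an already-filtered trial.

    ``labels`` maps activity_id to a binary label (fall=1). Frames whose
    LH_y is exactly zero (ratio undefined) are skipped with a warning.
    """
    frames = seq.frames
    if not frames:
        return []
    usable = []
    for f in frames:
        if f.LH_y == 0:
            logger.warning(
                "dropping frame t=%g of trial %s: LH_y=0, ratio undefined",
                f.t, f.trial_id,
            )
            continue
        usable.append(f)
    if not usable:
        return []
    times = [f.t for f in usable]
    a_n = [angle_to_origin(f.N_x, f.N_y) for f in usable]
    a_lsh = [angle_to_origin(f.LSh_x, f.LSh_y) for f in usable]
    a_lh = [angle_to_origin(f.LH_x, f.LH_y) for f in usable]
    dw_n = angular_rate(a_n, times)
    dw_lsh = angular_rate(a_lsh, times)
    dw_lh = angular_rate(a_lh, times)
    rows = []
    for k, f in enumerate(usable):
        try:
            label = labels[f.activity_id]
        except KeyError:
            raise DataError(f"activity_id {f.activity_id} missing from label map")
        rows.append(
            FeatureRow(
                t=f.t,
                subject_id=f.subject_id,
                trial_id=f.trial_id,
                label=int(label),
                N_x=f.N_x,
                N_y=f.N_y,
                A_N=a_n[k],
                A_LSh=a_lsh[k],
                A_LH=a_lh[k],
                dw_N=float(dw_n[k]),
                dw_LSh=float(dw_lsh[k]),
                dw_LH=float(dw_lh[k]),
                R=nose_hip_ratio(f.N_y, f.LH_y),
            )
        )
    return rows


def select_features(
    rows: Sequence[FeatureRow], spec: FeatureSetSpec | str
) -> np.ndarray:
    """Assemble the (n_rows, m) feature matrix for one model variant."""
    spec = resolve_feature_set(spec)
    return np.array(
        [[getattr(r, c) for c in spec.columns] for r in rows], dtype=float
    ).reshape(len(rows), spec.m)


def resolve_feature_set(spec: FeatureSetSpec | str) -> FeatureSetSpec:
    if isinstance(spec, FeatureSetSpec):
        return spec
    try:
        return FEATURE_SETS[spec]
    except KeyError:
        raise ConfigurationError(
            f"unknown feature set {spec!r}; expected one of {sorted(FEATURE_SETS)}"
        )


def write_features(rows: Sequence[FeatureRow], path: str | Path) -> Path:
    df = pd.DataFrame.from_records(
        [{c: getattr(r, c) for c in FEATURE_COLUMNS} for r in rows],
        columns=FEATURE_COLUMNS,
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_features(path: str | Path) -> list[FeatureRow]:
    """Read a feature-table CSV. The per-keypoint angles A_i are not stored
    (only their rates are model inputs); they are reloaded as NaN."""
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    return [
        FeatureRow(
            t=float(r.t), subject_id=str(r.subject_id), trial_id=str(r.trial_id),
            label=int(r.label), N_x=float(r.N_x), N_y=float(r.N_y),
            A_N=math.nan, A_LSh=math.nan, A_LH=math.nan,
            dw_N=float(r.dw_N), dw_LSh=float(r.dw_LSh), dw_LH=float(r.dw_LH),
            R=float(r.R),
        )
        for r in df.itertuples(index=False)
    ]
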