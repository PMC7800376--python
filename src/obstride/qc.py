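"""Tracking post-processing: masking, filtering, view merging, un-head-fixing.

The pipeline applies, in this fixed order, to every landmark in each view:

1. mask frames whose tracking confidence is below threshold;
2. mask frames that jump a large distance to *and* from their neighbours
   (single-frame outliers violate a velocity constraint);
3. temporal median filter (3 frames);
4. mask frames where the shared x coordinate disagrees between the two views;
5. linearly interpolate all masked values.

The two views are then merged into 3D positions: the top view contributes
x and z (vertical), the bottom view x and y (lateral); the shared x is the
mean of the two views.  Un-head-fixing adds the wheel displacement to x,
after which the obstacle is stationary and the mouse moves forward in space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

from .config import QCConfig
from .errors import AnalysisError, QCError
from .sim.session import RawSession

__all__ = ["CleanKinematics", "apply_qc", "unheadfix", "headfix",
           "wheel_velocity"]


@dataclass
class CleanKinematics:
    """Gap-free 3D landmark positions plus the wheel state.

    ``positions`` maps landmark name to an ``(n_frames, 3)`` array of
    x (forward), y (lateral), z (vertical above the wheel surface), all mm.
    ``frame`` is ``"head-fixed"`` (camera coordinates) or ``"world"``.
    """

    frame_rate: float
    positions: dict
    wheel_displacement: np.ndarray
    wheel_velocity: np.ndarray
    frame: str = "head-fixed"
    qc_report: dict | None = None
    camera_positions: dict | None = None  # kept by unheadfix for exact inversion

    @property
    def n_frames(self) -> int:
        return self.wheel_displacement.size

    def landmark(self, name: str) -> np.ndarray:
        return self.positions[name]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with a (landmark, coord) column MultiIndex."""
        cols, data = [], []
        for lm, arr in self.positions.items():
            for i, c in enumerate("xyz"):
                cols.append((lm, c))
                data.append(arr[:, i])
        return pd.DataFrame(np.column_stack(data),
                            columns=pd.MultiIndex.from_tuples(cols))


def _mask_jumps(xy: np.ndarray, mask: np.ndarray, thr: float) -> int:
    """Flag single-frame outliers: a large displacement in *and back out*.

    A frame is an outlier when both adjacent displacements exceed the
    threshold while the two-frame displacement bridging it does not --
    genuine fast swing motion moves on rather than returning.
    """
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    big_in = np.concatenate([[False], d > thr])        # jump into frame t
    big_out = np.concatenate([d > thr, [False]])       # jump out of frame t
    bridge = np.linalg.norm(xy[2:] - xy[:-2], axis=1)
    returns = np.concatenate([[False], bridge < thr, [False]])
    bad = big_in & big_out & returns
    n_new = int((bad & ~mask).sum())
    mask |= bad
    return n_new


def _median_filter_columns(a: np.ndarray, window: int) -> np.ndarray:
    return np.column_stack([
        median_filter(a[:, i], size=window, mode="nearest")
        for i in range(a.shape[1])])


def _interp_masked(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = a.copy()
    idx = np.arange(a.shape[0])
    good = ~mask
    if good.sum() == 0:
        return out
    for i in range(a.shape[1]):
        out[mask, i] = np.interp(idx[mask], idx[good], a[good, i])
    return out


def apply_qc(raw: RawSession, qc: QCConfig | None = None) -> CleanKinematics:
    """Run the five post-processing steps and merge the two views into 3D.

    Raises :class:`QCError` if more than ``qc.max_masked_fraction`` of a
    landmark's frames are masked in either view.
    """
    qc = qc or QCConfig()
    n = raw.n_frames
    report: dict[str, dict[str, int]] = {}
    merged: dict[str, np.ndarray] = {}

    for lm in raw.views["top"]:
        counts = {"confidence": 0, "jump": 0, "cross_view": 0}
        data, masks = {}, {}
        for view in ("top", "bottom"):
            arr = raw.views[view][lm]
            xy = arr[:, :2].astype(float)
            mask = arr[:, 2] < qc.confidence_threshold          # step 1
            counts["confidence"] += int(mask.sum())
            counts["jump"] += _mask_jumps(xy, mask,              # step 2
                                          qc.velocity_jump_threshold)
            filt = _interp_masked(xy, mask)
            filt = _median_filter_columns(filt, qc.median_window)  # step 3
            data[view], masks[view] = filt, mask
        dx = np.abs(data["top"][:, 0] - data["bottom"][:, 0])    # step 4
        bad_x = dx > qc.cross_view_x_tolerance
        counts["cross_view"] = int(bad_x.sum())
        for view in ("top", "bottom"):
            masks[view] |= bad_x
            frac = masks[view].mean()
            if frac > qc.max_masked_fraction:
                raise QCError(
                    f"landmark {lm!r} ({view} view): {frac:.0%} of frames "
                    "masked, exceeding the allowed fraction")
            data[view] = _interp_masked(data[view], masks[view])  # step 5
        x = 0.5 * (data["top"][:, 0] + data["bottom"][:, 0])
        z = data["top"][:, 1]
        y = data["bottom"][:, 1]
        merged[lm] = np.column_stack([x, y, z])
        report[lm] = counts

    vel = wheel_velocity(raw.wheel_displacement, raw.frame_rate)
    return CleanKinematics(frame_rate=raw.frame_rate, positions=merged,
                           wheel_displacement=raw.wheel_displacement.copy(),
                           wheel_velocity=vel, frame="head-fixed",
                           qc_report=report)


def unheadfix(kin: CleanKinematics) -> CleanKinematics:
    """Add the wheel displacement to x: camera frame -> world frame.

    In world coordinates the mouse advances past a stationary obstacle;
    stance paws are stationary.  y and z are unchanged.  Raises if the input
    is already in the world frame.
    """
    if kin.frame == "world":
        raise AnalysisError("kinematics already un-head-fixed")
    pos = {lm: arr + np.column_stack([kin.wheel_displacement,
                                      np.zeros(kin.n_frames),
                                      np.zeros(kin.n_frames)])
           for lm, arr in kin.positions.items()}
    return replace(kin, positions=pos, frame="world",
                   camera_positions=kin.positions)


def headfix(kin: CleanKinematics) -> CleanKinematics:
    """Exact inverse of :func:`unheadfix`."""
    if kin.frame != "world":
        raise AnalysisError("kinematics not in the world frame")
    if kin.camera_positions is not None:
        return replace(kin, positions=kin.camera_positions,
                       frame="head-fixed", camera_positions=None)
    pos = {lm: arr - np.column_stack([kin.wheel_displacement,
                                      np.zeros(kin.n_frames),
                                      np.zeros(kin.n_frames)])
           for lm, arr in kin.positions.items()}
    return replace(kin, positions=pos, frame="head-fixed")


def wheel_velocity(displacement: np.ndarray, frame_rate: float,
                   smooth_frames: int = 0) -> np.ndarray:
    """Central-difference wheel velocity in m/s from a mm displacement trace.

    Endpoints use one-sided differences.  ``smooth_frames > 1`` applies a
    moving-average filter of that width.
    """
    displacement = np.asarray(displacement, float)
    if displacement.size < 3:
        raise AnalysisError("need at least 3 frames to differentiate")
    v = np.gradient(displacement) * frame_rate / 1000.0
    if smooth_frames and smooth_frames > 1:
        v = uniform_filter1d(v, size=int(smooth_frames), mode="nearest")
    return v
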