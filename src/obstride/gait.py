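"""Stance detection, step segmentation, gait summaries and trial success.

Steps are represented as a :class:`pandas.DataFrame` (one row per step) with
columns::

    paw, lift_off_frame, touch_down_frame, lift_off_x, landing_x, length,
    peak_height, speed, is_control, is_over_obstacle, trial

Positions are world-frame mm; ``speed`` is the mean wheel velocity during the
swing in m/s.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import pearsonr

from .config import FOREPAWS, StanceConfig
from .errors import AnalysisError
from .qc import CleanKinematics

__all__ = ["detect_stance", "segment_steps", "extract_step_table",
           "control_steps", "paw_in_swing_at_contact", "trial_success",
           "hildebrand", "paw_obstacle_correlation", "height_at_distance",
           "BOTH_SWING", "BOTH_STANCE"]

BOTH_SWING = "BOTH_SWING"
BOTH_STANCE = "BOTH_STANCE"

STEP_COLUMNS = ["paw", "lift_off_frame", "touch_down_frame", "lift_off_x",
                "landing_x", "length", "peak_height", "speed", "is_control",
                "is_over_obstacle", "trial"]


def detect_stance(paw_z: np.ndarray, paw_vx: np.ndarray,
                  wheel_vel: np.ndarray, cfg: StanceConfig | None = None,
                  frame_rate: float = 250.0,
                  frame: str = "world") -> np.ndarray:
    """Boolean stance trace for one paw.

    A frame is stance when the paw's horizontal velocity matches the wheel
    (within ``velocity_tolerance``) and its height is within
    ``height_tolerance`` of the wheel surface; the raw trace is then
    debounced with a ~20 ms median filter.

    ``frame="world"`` interprets ``paw_vx`` (m/s) as world-frame velocity, so
    the criterion is ``|paw_vx| <= tol``.  ``frame="camera"`` interprets it as
    camera-frame velocity, where a stance paw moves backwards with the wheel
    surface: ``|paw_vx + wheel_vel| <= tol``.  The two are equivalent because
    ``v_world = v_camera + v_wheel``.
    """
    cfg = cfg or StanceConfig()
    paw_z = np.asarray(paw_z, float)
    paw_vx = np.asarray(paw_vx, float)
    wheel_vel = np.asarray(wheel_vel, float)
    if not (paw_z.shape == paw_vx.shape == wheel_vel.shape):
        raise AnalysisError("stance inputs must have equal length")
    if frame == "world":
        vel_ok = np.abs(paw_vx) <= cfg.velocity_tolerance
    elif frame == "camera":
        vel_ok = np.abs(paw_vx + wheel_vel) <= cfg.velocity_tolerance
    else:
        raise AnalysisError(f"unknown frame {frame!r}")
    stance = vel_ok & (paw_z <= cfg.height_tolerance)
    win = cfg.debounce_frames(frame_rate)
    if win > 1:
        stance = median_filter(stance.astype(np.int8), size=win,
                               mode="nearest").astype(bool)
    return stance


def segment_steps(stance: np.ndarray, x: np.ndarray, z: np.ndarray,
                  paw: str, wheel_vel: np.ndarray | None = None
                  ) -> pd.DataFrame:
    """One step per maximal swing interval of a debounced stance trace.

    Swing runs touching either end of the session are discarded.  Lift-off is
    the first swing frame, touch-down the first stance frame after the swing.
    """
    stance = np.asarray(stance, bool)
    n = stance.size
    d = np.diff(stance.astype(np.int8))
    lifts = np.nonzero(d == -1)[0] + 1      # stance -> swing
    downs = np.nonzero(d == 1)[0] + 1       # swing -> stance
    rows = []
    for lo in lifts:
        after = downs[downs > lo]
        if after.size == 0:
            continue                        # partial swing at the end
        td = int(after[0])
        if lo == 0:
            continue
        speed = float(np.mean(wheel_vel[lo:td])) if wheel_vel is not None \
            else np.nan
        rows.append({
            "paw": paw, "lift_off_frame": int(lo), "touch_down_frame": td,
            "lift_off_x": float(x[lo]), "landing_x": float(x[td]),
            "length": float(x[td] - x[lo]),
            "peak_height": float(np.max(z[lo:td])) if td > lo else 0.0,
            "speed": speed, "is_control": False, "is_over_obstacle": False,
            "trial": -1,
        })
    return pd.DataFrame(rows, columns=STEP_COLUMNS)


def extract_step_table(kin: CleanKinematics,
                       cfg: StanceConfig | None = None,
                       paws=("LF", "RF", "LH", "RH")) -> pd.DataFrame:
    """Stance-detect and segment every requested paw of a world-frame session."""
    if kin.frame != "world":
        raise AnalysisError("step extraction requires world-frame kinematics")
    dt = 1.0 / kin.frame_rate
    tables = []
    for paw in paws:
        arr = kin.landmark(paw)
        vx = np.gradient(arr[:, 0]) / dt / 1000.0   # m/s
        stance = detect_stance(arr[:, 2], vx, kin.wheel_velocity, cfg,
                               kin.frame_rate, frame="world")
        tables.append(segment_steps(stance, arr[:, 0], arr[:, 2], paw,
                                    kin.wheel_velocity))
    return pd.concat(tables, ignore_index=True)


def control_steps(steps: pd.DataFrame, contact_frame: int, paw: str
                  ) -> pd.DataFrame:
    """The two latest steps of ``paw`` completed before whisker contact.

    Returns what exists (with a warning) when fewer than two are available;
    the returned rows have ``is_control`` set.
    """
    sel = steps[(steps["paw"] == paw)
                & (steps["touch_down_frame"] < contact_frame)]
    sel = sel.sort_values("touch_down_frame").tail(2).copy()
    if len(sel) < 2:
        warnings.warn(f"only {len(sel)} control step(s) before frame "
                      f"{contact_frame} for paw {paw}", stacklevel=2)
    sel["is_control"] = True
    return sel


def paw_in_swing_at_contact(steps: pd.DataFrame, contact_frame: int) -> str:
    """The unique forepaw in swing at ``contact_frame``, or an exclusion code."""
    swinging = []
    for paw in FOREPAWS:
        sel = steps[(steps["paw"] == paw)
                    & (steps["lift_off_frame"] <= contact_frame)
                    & (steps["touch_down_frame"] > contact_frame)]
        if len(sel):
            swinging.append(paw)
    if len(swinging) == 1:
        return swinging[0]
    return BOTH_SWING if len(swinging) == 2 else BOTH_STANCE


def _merge_intervals(intervals):
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    out = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def trial_success(contact_intervals: dict, frame_rate: float
                  ) -> tuple[bool, dict]:
    """Overall and per-paw success of one trial.

    ``contact_intervals`` maps paw id to half-open frame ranges of
    paw--obstacle contact.  The trial succeeds when the total contact time
    (summed over paws, overlaps within a paw merged) is at most 20 ms;
    an individual paw succeeds only with zero contact.
    """
    total_frames = 0
    per_paw = {}
    for paw, ivs in contact_intervals.items():
        merged = _merge_intervals(ivs)
        frames = sum(b - a for a, b in merged)
        total_frames += frames
        per_paw[paw] = frames == 0
    ok = total_frames * 1000.0 / frame_rate <= 20.0
    return ok, per_paw


def hildebrand(steps: pd.DataFrame, reference_limb: str = "LH",
               n_bins: int = 100, min_strides: int = 10,
               n_frames: int | None = None) -> pd.DataFrame:
    """Stance-probability raster of every limb over normalized stride phase.

    Each stride of the reference limb (touch-down to touch-down) defines
    phase [0, 1); the stance indicator of every limb is sampled on a fixed
    phase grid and averaged across strides.  Returns a DataFrame indexed by
    limb with one column per phase bin.  In a trot the diagonal partner's
    band coincides with the reference and the opposite pair is offset by half
    a cycle; the row mean of each limb approximates its duty factor.
    """
    ref = steps[steps["paw"] == reference_limb].sort_values("touch_down_frame")
    if len(ref) < min_strides + 1:
        raise AnalysisError(
            f"need at least {min_strides} complete strides of "
            f"{reference_limb}; have {max(len(ref) - 1, 0)}")
    if n_frames is None:
        n_frames = int(steps["touch_down_frame"].max()) + 1
    limbs = list(dict.fromkeys(steps["paw"]))
    stance_traces = {}
    for limb in limbs:
        tab = steps[steps["paw"] == limb]
        tr = np.ones(n_frames, bool)
        for _, r in tab.iterrows():
            tr[int(r["lift_off_frame"]):int(r["touch_down_frame"])] = False
        stance_traces[limb] = tr

    phases = (np.arange(n_bins) + 0.5) / n_bins
    acc = {limb: np.zeros(n_bins) for limb in limbs}
    count = 0
    tds = ref["touch_down_frame"].to_numpy()
    for f0, f1 in zip(tds[:-1], tds[1:]):
        if f1 - f0 < 2 or f1 > n_frames:
            continue
        sample = np.minimum((f0 + phases * (f1 - f0)).astype(int), n_frames - 1)
        for limb in limbs:
            acc[limb] += stance_traces[limb][sample]
        count += 1
    if count < min_strides:
        raise AnalysisError("too few usable strides for a Hildebrand plot")
    mat = pd.DataFrame({limb: acc[limb] / count for limb in limbs}).T
    mat.columns = phases
    return mat


def height_at_distance(x: np.ndarray, z: np.ndarray, step_row,
                       obstacle_x: float, distance: float = 8.0
                       ) -> float:
    """Paw height, linearly interpolated where x crosses
    ``obstacle_x - distance`` within the step's swing."""
    lo, td = int(step_row["lift_off_frame"]), int(step_row["touch_down_frame"])
    target = obstacle_x - distance
    xs, zs = x[lo:td + 1], z[lo:td + 1]
    idx = np.nonzero((xs[:-1] <= target) & (xs[1:] > target))[0]
    if idx.size == 0:
        return np.nan
    i = int(idx[0])
    f = (target - xs[i]) / max(xs[i + 1] - xs[i], 1e-9)
    return float(zs[i] + f * (zs[i + 1] - zs[i]))


def paw_obstacle_correlation(paw_heights, obstacle_heights) -> float:
    """Pearson correlation between paw height at 8 mm before the obstacle and
    obstacle height, across trials."""
    h = np.asarray(paw_heights, float)
    o = np.asarray(obstacle_heights, float)
    good = np.isfinite(h) & np.isfinite(o)
    if good.sum() < 3:
        raise AnalysisError("need at least 3 trials for a correlation")
    return float(pearsonr(h[good], o[good])[0])
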