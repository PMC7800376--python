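"""End-to-end helpers: from raw sessions to step tables and decision trials.

These functions glue the stages together the way a session is actually
analysed: QC -> un-head-fix -> stance/step segmentation -> contact-time
feature extraction -> landing prediction and labeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FOREPAWS, QCConfig, StanceConfig
from .decision import assemble_decision_dataset
from .errors import AnalysisError
from .gait import (BOTH_STANCE, BOTH_SWING, control_steps, extract_step_table,
                   paw_in_swing_at_contact)
from .qc import CleanKinematics, apply_qc, unheadfix
from .sim.session import GroundTruth, RawSession

__all__ = ["process_session", "extract_decision_trials",
           "session_control_steps"]


def process_session(raw: RawSession, qc: QCConfig | None = None,
                    stance: StanceConfig | None = None
                    ) -> tuple[CleanKinematics, pd.DataFrame]:
    """QC, un-head-fix and segment a raw session.

    Returns world-frame kinematics and the step table for all four paws.
    """
    kin = unheadfix(apply_qc(raw, qc))
    steps = extract_step_table(kin, stance)
    return kin, steps


def session_control_steps(steps: pd.DataFrame, contact_frames,
                          paws=FOREPAWS) -> pd.DataFrame:
    """Collect the two pre-contact control steps per paw for every trial."""
    import warnings
    out = []
    for f_c in contact_frames:
        for paw in paws:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs = control_steps(steps, int(f_c), paw)
            out.append(cs)
    if not out:
        return steps.iloc[0:0]
    cat = pd.concat(out).drop_duplicates(
        subset=["paw", "lift_off_frame"]).reset_index(drop=True)
    return cat


def extract_decision_trials(kin: CleanKinematics, steps: pd.DataFrame,
                            truth: GroundTruth | None = None,
                            contact_frames=None,
                            trials: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure the eight decision features at whisker contact per trial.

    Contact frames come either from the planted truth or from an upstream
    detector (``contact_frames``).  Returns ``(trial_table, control_steps)``
    shaped like the trial-level cohort tables, with world-frame lift-off and
    obstacle positions, so :func:`obstride.decision.assemble_decision_dataset`
    applies unchanged.
    """
    if kin.frame != "world":
        raise AnalysisError("decision features require world-frame kinematics")
    if contact_frames is None:
        if truth is None:
            raise AnalysisError("need either planted truth or contact frames")
        tt = truth.trials
        contact_frames = tt["contact_frame"].to_numpy(int)
        obstacle_x = tt["obstacle_x_world"].to_numpy(float)
        heights = tt["obstacle_height"].to_numpy(float)
        trial_ids = tt["trial"].to_numpy(int)
    else:
        if trials is None:
            raise AnalysisError("trial metadata required with detector frames")
        contact_frames = np.asarray(contact_frames, int)
        obstacle_x = trials["obstacle_x_world"].to_numpy(float)
        heights = trials["obstacle_height_mm"].to_numpy(float)
        trial_ids = trials["trial"].to_numpy(int)

    dt = 1.0 / kin.frame_rate
    nose = kin.landmark("nose")
    tail = kin.landmark("tail_base")
    angle = np.degrees(np.arctan2(
        nose[:, 1] - tail[:, 1], nose[:, 0] - tail[:, 0]))

    paw_arr = {p: kin.landmark(p) for p in FOREPAWS}
    paw_vx = {p: np.gradient(a[:, 0]) / dt for p, a in paw_arr.items()}
    paw_vz = {p: np.gradient(a[:, 2]) / dt for p, a in paw_arr.items()}

    rows = []
    for i, f_c in enumerate(contact_frames):
        f_c = int(f_c)
        row = {"trial": int(trial_ids[i]), "contact_frame": f_c,
               "obstacle_height": float(heights[i]),
               "obstacle_x_world": float(obstacle_x[i])}
        paw = paw_in_swing_at_contact(steps, f_c)
        if paw in (BOTH_SWING, BOTH_STANCE):
            row.update(exclusion=paw)
            rows.append(row)
            continue
        sel = steps[(steps["paw"] == paw)
                    & (steps["lift_off_frame"] <= f_c)
                    & (steps["touch_down_frame"] > f_c)]
        st = sel.iloc[0]
        arr = paw_arr[paw]
        nose_x = nose[f_c, 0]
        row.update({
            "exclusion": "",
            "swing_paw": paw,
            "obstacle_x": float(obstacle_x[i] - nose_x),
            "obstacle_z": float(heights[i]),
            "paw_x": float(arr[f_c, 0] - nose_x),
            "paw_z": float(arr[f_c, 2]),
            "paw_vx": float(paw_vx[paw][f_c]),
            "paw_vz": float(paw_vz[paw][f_c]),
            "wheel_velocity": float(kin.wheel_velocity[f_c]),
            "body_angle": float(angle[f_c]),
            "tail_height": float(tail[f_c, 2]),
            "lift_off_x": float(st["lift_off_x"]),
            "actual_landing": float(st["landing_x"] - obstacle_x[i]),
        })
        rows.append(row)
    trial_table = pd.DataFrame(rows)
    # decision features and landing prediction use world coordinates here;
    # override obstacle_x for the landing model with the world value
    trial_table["obstacle_x_model"] = trial_table["obstacle_x_world"]
    cs = session_control_steps(steps, contact_frames)
    cs = cs.rename(columns={"speed": "wheel_velocity"})
    return trial_table, cs


def build_decision_dataset(session_tables: list,
                           min_control_steps: int = 10) -> pd.DataFrame:
    """Label trials across sessions of one mouse.

    ``session_tables`` is a list of ``(mouse, session, trial_table,
    control_steps)`` tuples from :func:`extract_decision_trials`.
    """
    trials_l, steps_l = [], []
    for mouse, session, tt, cs in session_tables:
        tt = tt.copy()
        cs = cs.copy()
        tt["mouse"], tt["session"] = mouse, session
        cs["mouse"], cs["session"] = mouse, session
        # world-frame landing prediction
        tt = tt.rename(columns={"obstacle_x": "obstacle_x_nose"})
        tt = tt.rename(columns={"obstacle_x_model": "obstacle_x"})
        trials_l.append(tt)
        steps_l.append(cs)
    trials = pd.concat(trials_l, ignore_index=True)
    steps = pd.concat(steps_l, ignore_index=True)
    ds = assemble_decision_dataset(trials, steps,
                                   min_control_steps=min_control_steps)
    return ds.rename(columns={"obstacle_x": "obstacle_x_world_model",
                              "obstacle_x_nose": "obstacle_x"})
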