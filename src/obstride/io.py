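"""Reading and writing sessions, kinematics and step tables.

Sessions are stored either as a directory of CSV files or as one HDF5 file
with groups ``/tracking/top``, ``/tracking/bottom``, ``/wheel``, ``/trials``
and (for simulated sessions) ``/truth``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .qc import CleanKinematics
from .sim.session import GroundTruth, RawSession

__all__ = ["save_session_csv", "load_session_csv", "save_session_h5",
           "load_session_h5", "save_kinematics_h5", "save_steps_csv",
           "load_steps_csv"]

_TRIAL_COLS = ["trial", "obstacle_height_mm", "engage_position_m", "light",
               "condition"]


def save_session_csv(raw: RawSession, out_dir, truth: GroundTruth | None = None
                     ) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for view in raw.views:
        raw.table(view).to_csv(out / f"tracking_{view}.csv", index=False)
    pd.DataFrame({"frame": np.arange(raw.n_frames),
                  "displacement_mm": raw.wheel_displacement}
                 ).to_csv(out / "wheel.csv", index=False)
    cols = [c for c in _TRIAL_COLS if c in raw.trials.columns]
    extra = [c for c in raw.trials.columns if c not in cols]
    raw.trials[cols + extra].to_csv(out / "trials.csv", index=False)
    with open(out / "meta.csv", "w") as fh:
        fh.write(f"frame_rate\n{raw.frame_rate}\n")
    if truth is not None:
        truth.trials.to_csv(out / "truth_trials.csv", index=False)
        truth.steps.to_csv(out / "truth_steps.csv", index=False)
    return out


def load_session_csv(in_dir) -> RawSession:
    src = Path(in_dir)
    frame_rate = float(pd.read_csv(src / "meta.csv")["frame_rate"].iloc[0])
    wheel = pd.read_csv(src / "wheel.csv")["displacement_mm"].to_numpy()
    views = {}
    for view in ("top", "bottom"):
        tab = pd.read_csv(src / f"tracking_{view}.csv")
        views[view] = {
            str(lm): grp.sort_values("frame")[["x", "y", "confidence"]]
            .to_numpy(float)
            for lm, grp in tab.groupby("landmark")}
    trials = pd.read_csv(src / "trials.csv")
    return RawSession(frame_rate=frame_rate, wheel_displacement=wheel,
                      views=views, trials=trials)


def _write_df(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    g = group.create_group(name)
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object:
            data = data.astype(str)
            g.create_dataset(col, data=np.char.encode(data, "utf-8"))
        else:
            g.create_dataset(col, data=data)
    g.attrs["columns"] = list(df.columns)


def _read_df(group: h5py.Group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    data = {}
    for c in cols:
        arr = group[c][()]
        if arr.dtype.kind == "S":
            arr = np.char.decode(arr, "utf-8")
        data[c] = arr
    return pd.DataFrame(data)


def save_session_h5(raw: RawSession, path,
                    truth: GroundTruth | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = raw.frame_rate
        trk = f.create_group("tracking")
        for view, d in raw.views.items():
            g = trk.create_group(view)
            for lm, arr in d.items():
                g.create_dataset(lm, data=arr)
        f.create_dataset("wheel/displacement_mm", data=raw.wheel_displacement)
        _write_df(f, "trials", raw.trials)
        if truth is not None:
            tg = f.create_group("truth")
            _write_df(tg, "trials", truth.trials.fillna(np.nan))
            _write_df(tg, "steps", truth.steps)
            for k, v in truth.step_law.items():
                tg.attrs[k] = v
            tg.attrs["temperature"] = truth.temperature
    return path


def load_session_h5(path) -> tuple[RawSession, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        views = {view: {lm: f["tracking"][view][lm][()]
                        for lm in f["tracking"][view]}
                 for view in f["tracking"]}
        raw = RawSession(frame_rate=float(f.attrs["frame_rate"]),
                         wheel_displacement=f["wheel/displacement_mm"][()],
                         views=views, trials=_read_df(f["trials"]))
        truth = None
        if "truth" in f:
            tg = f["truth"]
            truth = GroundTruth(
                trials=_read_df(tg["trials"]), steps=_read_df(tg["steps"]),
                step_law={k: tg.attrs[k] for k in
                          ("intercept", "slope", "residual_sd")},
                temperature=float(tg.attrs["temperature"]))
    return raw, truth


def save_kinematics_h5(kin: CleanKinematics, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group(f"kinematics/{kin.frame.replace('-', '_')}")
        for lm, arr in kin.positions.items():
            g.create_dataset(lm, data=arr)
        f.create_dataset("wheel/displacement_mm", data=kin.wheel_displacement)
        f.create_dataset("wheel/velocity_mps", data=kin.wheel_velocity)
        f.attrs["frame_rate"] = kin.frame_rate
        f.attrs["frame"] = kin.frame
    return path


def save_steps_csv(steps: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    steps.to_csv(path, index=False)
    return path


def load_steps_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
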