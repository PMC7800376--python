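"""Frame-level simulation of a head-fixed running-wheel session.

A session is a trot gait on a wheel, sampled at 250 Hz, with obstacle trials
interleaved the way the behavioural task schedules them (three obstacles per
reward cycle, jittered engagement positions and start distances, randomized
heights and lighting).  The simulator plants

* the step-length law ``L = a + b*v + eps`` (per step, against stride speed);
* body-relative landing placement as a stationary AR(1) chain whose
  increments are exactly the step-length residuals ``eps``;
* whisker contact when the obstacle reaches a speed-dependent position
  anterior of the nose;
* a shorten/lengthen decision for the forepaw in swing at contact, applied to
  the trajectory starting ``planted_latency`` ms after contact;
* apex heights that track obstacle height on steps that cross the obstacle.

Everything planted is reported in :class:`GroundTruth` so downstream stages
can be verified frame-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from ..config import FOREPAWS, GeneratorConfig, PAWS
from ..errors import ConfigurationError
from .decisions import (_draw_actual_landing, _unmodified_probability,
                        lengthen_probability, resolve_temperature)

__all__ = ["RawSession", "GroundTruth", "generate_session"]

#: trot phase offsets: diagonal pairs in phase, the two pairs antiphase
PHASE_OFFSETS = {"LF": 0.0, "RH": 0.0, "RF": 0.5, "LH": 0.5}
#: lateral (bottom-view) positions of the landmarks, mm from the midline
LATERAL = {"LF": 8.0, "RF": -8.0, "LH": 10.0, "RH": -10.0,
           "tail_base": 0.0, "tail_mid": 0.0, "nose": 0.0, "obstacle": 0.0}
_OBSTACLE_HOME_X = 330.0  # camera-frame parking position when not engaged


@dataclass
class RawSession:
    """Simulated (or loaded) two-view landmark tracking for one session."""

    frame_rate: float
    wheel_displacement: np.ndarray            # mm, cumulative, per frame
    views: dict                               # view -> landmark -> (n, 3) [x, y, conf]
    trials: pd.DataFrame
    artifact_log: pd.DataFrame | None = None  # filled by inject_tracking_artifacts
    clean_views: dict | None = None           # pre-artifact copy, for QC tests

    @property
    def n_frames(self) -> int:
        return self.wheel_displacement.size

    @property
    def landmarks(self) -> tuple:
        return tuple(self.views["top"])

    def table(self, view: str) -> pd.DataFrame:
        """Long-format landmark table (frame, landmark, x, y, confidence)."""
        rows = []
        for lm, arr in self.views[view].items():
            rows.append(pd.DataFrame({
                "frame": np.arange(self.n_frames),
                "landmark": lm,
                "x": arr[:, 0], "y": arr[:, 1], "confidence": arr[:, 2],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class GroundTruth:
    """Per-trial and per-step planted truths of one simulated session."""

    trials: pd.DataFrame   # contact frames, labels, planted distances, onsets
    steps: pd.DataFrame    # planted lift-off / landing schedule per paw
    step_law: dict         # {"intercept", "slope", "residual_sd"}
    temperature: float = float("nan")


def _phase_to_time(phases, stride_bounds):
    """Time of a (fractional) global stride phase; stride k spans phase [k, k+1)."""
    grid = np.arange(stride_bounds.size)
    return np.interp(phases, grid, stride_bounds)


def _stride_speeds(config: GeneratorConfig, n: int, rng) -> np.ndarray:
    """Slowly drifting per-stride speeds with the configured marginal SD."""
    phi = config.speed_modulation_ar
    innov_sd = config.speed_sd * math.sqrt(1.0 - phi * phi)
    v = np.empty(n)
    x = rng.normal(0.0, config.speed_sd)
    for k in range(n):
        v[k] = config.mean_speed + x
        x = phi * x + rng.normal(0.0, innov_sd)
    return np.clip(v, 0.15, None)


def _ar1(n, rho, sd, rng):
    out = np.empty(n)
    x = rng.normal(0.0, sd)
    innov = sd * math.sqrt(1.0 - rho * rho)
    for k in range(n):
        out[k] = x
        x = rho * x + rng.normal(0.0, innov)
    return out


def _ar1_cumsum(innov, rho):
    # x_t = rho * x_{t-1} + e_t  computed via the scaling trick
    n = innov.size
    powers = rho ** np.arange(n)
    with np.errstate(over="ignore", under="ignore"):
        scaled = innov / powers
        out = np.cumsum(scaled) * powers
    if not np.all(np.isfinite(out)):  # long traces underflow; fall back to loop
        out = np.empty(n)
        x = 0.0
        for t in range(n):
            x = rho * x + innov[t]
            out[t] = x
    return out


def _ar1_frames_stable(n, rho, sd, rng, block=2048):
    """AR(1) with marginal ``sd`` computed blockwise to avoid underflow."""
    out = np.empty(n)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    x = rng.normal(0.0, sd)
    for start in range(0, n, block):
        m = min(block, n - start)
        e = rng.normal(0.0, innov_sd, m)
        e[0] += rho * x
        seg = _ar1_cumsum(e, rho)
        out[start:start + m] = seg
        x = seg[-1]
    return out


def generate_session(config: GeneratorConfig, seed: int | None = None
                     ) -> tuple[RawSession, GroundTruth]:
    """Simulate one session; bit-identical for a given ``(config, seed)``.

    Returns the raw two-view tracking tables (confidence 1 everywhere; use
    :func:`obstride.sim.inject_tracking_artifacts` to corrupt them) and the
    planted ground truth.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigurationError("seed: a seed must be provided")
    cfg = config
    rng_gait = np.random.default_rng([seed, 1])
    rng_noise = np.random.default_rng([seed, 2])
    tau = resolve_temperature(cfg)
    if not cfg.whiskers_present:
        tau = tau * cfg.whiskerless_temperature_factor
    rate, dt = cfg.frame_rate, 1.0 / cfg.frame_rate

    # ---- trial schedule in wheel distance --------------------------------
    per_cycle = len(cfg.engage_distances)
    engage_m, start_mm = [], []
    for k in range(cfg.n_trials):
        rng_t = np.random.default_rng([seed, 7, k])
        r, i = divmod(k, per_cycle)
        engage_m.append(cfg.reward_distance * r + cfg.engage_distances[i]
                        + rng_t.uniform(-cfg.engage_jitter, cfg.engage_jitter))
        start_mm.append(1000.0 * (cfg.obstacle_start_distance
                                  + rng_t.uniform(-cfg.obstacle_start_jitter,
                                                  cfg.obstacle_start_jitter)))
    target_mm = (engage_m[-1] * 1000.0 + start_mm[-1] + 300.0) if cfg.n_trials \
        else 2000.0

    # ---- strides ---------------------------------------------------------
    l_min = max(5.0, cfg.predicted_step_length(max(0.15, cfg.mean_speed
                                                   - 4 * cfg.speed_sd)))
    n_strides = int(target_mm / l_min) + 8
    v_stride = _stride_speeds(cfg, n_strides, rng_gait)
    l_bar = cfg.predicted_step_length(v_stride)
    # keep only the strides needed to cover the trial schedule
    needed = int(np.searchsorted(np.cumsum(l_bar), target_mm + 200.0)) + 4
    n_strides = min(n_strides, needed)
    v_stride, l_bar = v_stride[:n_strides], l_bar[:n_strides]
    t_stride = l_bar / (1000.0 * v_stride)
    stride_bounds = np.concatenate([[0.0], np.cumsum(t_stride)])
    n_frames = int(stride_bounds[-1] * rate)
    t_frames = np.arange(n_frames) * dt

    # per-frame wheel speed: piecewise-constant per stride, lightly smoothed
    stride_of_frame = np.searchsorted(stride_bounds, t_frames, side="right") - 1
    v_frames = v_stride[np.clip(stride_of_frame, 0, n_strides - 1)]
    v_frames = uniform_filter1d(v_frames, size=25, mode="nearest")
    displacement = np.concatenate([[0.0], np.cumsum(v_frames[:-1])]) * 1000.0 * dt

    def d_of_t(t):
        return np.interp(t, t_frames, displacement)

    def v_of_t(t):
        return np.interp(t, t_frames, v_frames)

    t_end = t_frames[-1]

    # ---- obstacle trials -------------------------------------------------
    trial_rows, truth_rows = [], []
    for k in range(cfg.n_trials):
        rng_t = np.random.default_rng([seed, 7, k])
        rng_t.uniform(size=2)  # consume the jitter draws made above
        engage_mm = engage_m[k] * 1000.0
        if engage_mm > displacement[-1] - start_mm[k] - 150.0:
            break
        t_engage = np.interp(engage_mm, displacement, t_frames)
        obstacle_x = d_of_t(t_engage) + start_mm[k]
        height = rng_t.uniform(*cfg.obstacle_height_range)
        light = bool(rng_t.random() < cfg.light_on_probability)
        v_ref = v_of_t(np.interp(obstacle_x - cfg.whisker_reach,
                                 displacement, t_frames))
        contact_noise = cfg.contact_noise_sd
        if not cfg.whiskers_present:
            contact_noise *= cfg.whiskerless_landing_noise_factor
        contact_pos = (cfg.whisker_reach
                       + cfg.contact_speed_slope * (v_ref - cfg.mean_speed)
                       + rng_t.normal(0.0, contact_noise))
        t_contact = np.interp(obstacle_x - contact_pos, displacement, t_frames)
        trial_rows.append({
            "trial": k, "obstacle_height_mm": height,
            "engage_position_m": engage_m[k], "light": light,
            "condition": "whiskers" if cfg.whiskers_present else "no_whiskers",
            "engage_frame": int(round(t_engage * rate)),
            "obstacle_x_world": obstacle_x,
        })
        truth_rows.append({
            "trial": k, "t_engage": t_engage, "t_contact": t_contact,
            "contact_frame": int(round(t_contact * rate)),
            "obstacle_x_world": obstacle_x, "obstacle_height": height,
            "contact_position": contact_pos, "wheel_speed": v_of_t(t_contact),
        })
    trials = pd.DataFrame(trial_rows)
    truth = pd.DataFrame(truth_rows)

    # ---- per-limb step schedule ------------------------------------------
    # cycle c of limb p spans global phase [c + psi_p, c + 1 + psi_p)
    steps: dict[str, pd.DataFrame] = {}
    for paw in PAWS:
        psi = PHASE_OFFSETS[paw]
        base = cfg.forepaw_landing_offset if paw in FOREPAWS \
            else cfg.hindpaw_landing_offset
        n_cyc = n_strides - 2
        cyc = np.arange(n_cyc)
        t_stance = _phase_to_time(cyc + psi, stride_bounds)
        t_swing = _phase_to_time(cyc + psi + cfg.duty_factor, stride_bounds)
        t_land = _phase_to_time(cyc + psi + 1.0, stride_bounds)
        keep = t_land < t_end - dt
        cyc, t_stance, t_swing, t_land = (a[keep] for a in
                                          (cyc, t_stance, t_swing, t_land))
        xi = _ar1(cyc.size, cfg.placement_ar, cfg.placement_sd, rng_gait)
        landing_x = d_of_t(t_land) + base + xi
        v_sw = v_of_t(t_swing)
        l_pred = cfg.predicted_step_length(v_sw)
        apex = cfg.swing_height * l_pred / cfg.reference_step_length
        steps[paw] = pd.DataFrame({
            "paw": paw, "cycle": cyc, "t_stance": t_stance, "t_swing": t_swing,
            "t_land": t_land, "landing_x": landing_x, "speed": v_sw,
            "l_pred": l_pred, "apex": apex, "modified": False,
            "crosses_obstacle": False, "trial": -1,
        })

    # ---- decisions: modify the forepaw in swing at contact ---------------
    if len(truth):
        truth["swing_paw"] = ""
        truth["exclusion"] = ""
        truth["true_label"] = ""
        truth["executed"] = False
        truth["executed_mode"] = ""
        truth["true_dpred"] = np.nan
        truth["actual_landing"] = np.nan
        truth["onset_frame"] = np.nan
        truth["swing_phase"] = np.nan
    for idx, tr in truth.iterrows():
        rng_t = np.random.default_rng([seed, 9, int(tr["trial"])])
        t_c = tr["t_contact"]
        in_swing = []
        for paw in FOREPAWS:
            tab = steps[paw]
            j = np.searchsorted(tab["t_land"].to_numpy(), t_c, side="right")
            if j < len(tab) and tab["t_swing"].iloc[j] <= t_c < tab["t_land"].iloc[j]:
                in_swing.append((paw, j))
        if len(in_swing) != 1:
            truth.at[idx, "exclusion"] = ("BOTH_SWING" if len(in_swing) == 2
                                          else "BOTH_STANCE")
            continue
        paw, j = in_swing[0]
        tab = steps[paw]
        if j == 0:
            truth.at[idx, "exclusion"] = "NO_LIFTOFF"
            continue
        lift_x = tab["landing_x"].iloc[j - 1]
        l_pred = tab["l_pred"].iloc[j]
        dpred = lift_x + l_pred - tr["obstacle_x_world"]
        u = ((t_c - tab["t_swing"].iloc[j])
             / (tab["t_land"].iloc[j] - tab["t_swing"].iloc[j]))
        p_len = lengthen_probability(dpred, tr["obstacle_height"], cfg, tau)
        unmod = rng_t.random() < _unmodified_probability(
            np.asarray(dpred), cfg, tau)
        if unmod:
            label = "unmodified"
        else:
            label = "lengthened" if rng_t.random() < p_len else "shortened"
        target = float(_draw_actual_landing(
            np.atleast_1d(np.asarray(dpred, float)),
            np.array([label], dtype=object),
            np.array([label == "unmodified"]), cfg, rng_t)[0])
        onset_frames = round(cfg.planted_latency * rate / 1000.0)
        t_on = (tr["contact_frame"] + onset_frames) * dt
        tab = steps[paw]
        t0, t1p = tab["t_swing"].iloc[j], tab["t_land"].iloc[j]
        x_planned = tab["landing_x"].iloc[j]
        t_sw = t1p - t0

        truth.at[idx, "swing_paw"] = paw
        truth.at[idx, "true_label"] = label
        truth.at[idx, "true_dpred"] = dpred
        truth.at[idx, "swing_phase"] = u

        if label == "unmodified":
            truth.at[idx, "actual_landing"] = x_planned - tr["obstacle_x_world"]
            continue
        in_flight = t_on <= t1p - 2 * dt
        if in_flight:
            # correct the ongoing swing: size scales with the controllable
            # time that remains after the reaction onset
            gain = min(1.0, (t1p - t_on) / (0.6 * t_sw))
            x_new = x_planned + gain * (tr["obstacle_x_world"] + target
                                        - x_planned)
            # position at onset along the planned profile: cannot land
            # behind it
            u_on = np.clip((t_on - t0) / t_sw, 0.0, 1.0)
            s_on = 0.5 * (1 - np.cos(np.pi * u_on))
            w_on = np.clip((u_on - 0.5) / 0.5, 0.0, None) ** 2
            l_pred_step = tab["l_pred"].iloc[j]
            x_on = (lift_x + s_on * l_pred_step
                    + w_on * (x_planned - lift_x - l_pred_step))
            x_new = max(x_new, x_on + 0.5)

            truth.at[idx, "executed"] = True
            truth.at[idx, "executed_mode"] = "in_flight"
            truth.at[idx, "actual_landing"] = x_new - tr["obstacle_x_world"]
            truth.at[idx, "onset_frame"] = tr["contact_frame"] + onset_frames
            tab.loc[tab.index[j], ["modified", "trial"]] = True, int(tr["trial"])
            tab.loc[tab.index[j], "t_onset"] = t_on
            tab.loc[tab.index[j], "x_planned"] = x_planned
            tab.loc[tab.index[j], "apex_planned"] = tab["apex"].iloc[j]
            tab.loc[tab.index[j], "t_land_planned"] = t1p
            # lengthened steps extend the swing at the mean swing speed
            if x_new > x_planned:
                extra = (x_new - x_planned) / (l_pred_step / t_sw)
                limit = (tab["t_stance"].iloc[j + 1] + cfg.duty_factor
                         * (tab["t_land"].iloc[j + 1]
                            - tab["t_stance"].iloc[j + 1])
                         - 2 * dt) if j + 1 < len(tab) else t_end
                tab.loc[tab.index[j], "t_land"] = min(
                    t1p + min(extra, 0.6 * t_sw), limit)
            tab.loc[tab.index[j], "landing_x"] = x_new
        else:
            # the paw lands before the correction can act: the decision
            # carries over to the paw's next step, which lifts off early
            # (at the reaction onset) and lands at the decided position
            if j + 1 >= len(tab) - 1:
                truth.at[idx, "actual_landing"] = (x_planned
                                                  - tr["obstacle_x_world"])
                continue
            jn = j + 1
            t_lift_new = max(t_on - dt, t1p + 2 * dt)
            t_land_next = tab["t_land"].iloc[jn]
            if t_lift_new >= t_land_next - 4 * dt:
                truth.at[idx, "actual_landing"] = (x_planned
                                                   - tr["obstacle_x_world"])
                continue
            x_next_target = tr["obstacle_x_world"] + target
            x_next_target = max(x_next_target, x_planned + 2.0)
            truth.at[idx, "executed"] = True
            truth.at[idx, "executed_mode"] = "next_step"
            truth.at[idx, "actual_landing"] = (x_next_target
                                               - tr["obstacle_x_world"])
            # the early lift is the first departure from the unmodified
            # continuation; when it cannot happen before the planted onset
            # (the paw is still landing), the realized onset is later
            if t_lift_new <= t_on - dt + 1e-9:
                truth.at[idx, "onset_frame"] = (tr["contact_frame"]
                                                + onset_frames)
            else:
                truth.at[idx, "onset_frame"] = int(
                    np.ceil(t_lift_new * rate)) + 1
            tab.loc[tab.index[jn], ["modified", "trial"]] = True, int(tr["trial"])
            tab.loc[tab.index[jn], "t_swing"] = t_lift_new
            tab.loc[tab.index[jn], "t_onset"] = t_lift_new
            tab.loc[tab.index[jn], "landing_x"] = x_next_target

    # ---- obstacle-crossing steps: apex tracks obstacle height ------------
    for paw in PAWS:
        tab = steps[paw]
        lift = tab["landing_x"].shift(1)
        for idx2, tr in truth.iterrows():
            active = ((tab["t_swing"] >= tr["t_engage"])
                      & (tab["t_land"] <= tr["t_contact"] + 0.6)
                      & (lift < tr["obstacle_x_world"])
                      & (tab["landing_x"] > tr["obstacle_x_world"]))
            if active.any():
                rng_t = np.random.default_rng([seed, 11, int(tr["trial"]),
                                               PAWS.index(paw)])
                sel = tab.index[active]
                tab.loc[sel, "apex"] = (tr["obstacle_height"]
                                        + cfg.obstacle_clearance
                                        + rng_t.normal(0, cfg.clearance_noise_sd,
                                                       active.sum()).clip(-3, None))
                tab.loc[sel, "crosses_obstacle"] = True
                if (tab.loc[sel, "trial"] == -1).all():
                    tab.loc[sel, "trial"] = int(tr["trial"])

    # ---- rasterise limb trajectories -------------------------------------
    world_x = {}
    world_z = {}
    step_rows = []
    for paw in PAWS:
        tab = steps[paw].reset_index(drop=True)
        m = len(tab)
        col = {c: tab[c].to_numpy() for c in
               ("t_swing", "t_land", "landing_x", "l_pred", "apex", "speed",
                "cycle", "trial")}
        c_mod = tab["modified"].to_numpy(bool)
        c_cross = tab["crosses_obstacle"].to_numpy(bool)

        def _opt(name):
            return tab[name].to_numpy(float) if name in tab.columns \
                else np.full(m, np.nan)

        c_onset = _opt("t_onset")
        c_xplan = _opt("x_planned")
        c_apexplan = _opt("apex_planned")
        c_tlandplan = _opt("t_land_planned")

        x = np.empty(n_frames)
        z = np.zeros(n_frames)
        first = int(np.ceil(col["t_swing"][0] * rate))
        x[:first] = col["landing_x"][0] - col["l_pred"][0]
        prev_x = x[0]
        for j in range(m):
            f_sw = int(np.ceil(col["t_swing"][j] * rate))
            f_ld = int(np.ceil(col["t_land"][j] * rate))
            f_next = int(np.ceil(col["t_swing"][j + 1] * rate)) \
                if j + 1 < m else n_frames
            f_ld = min(f_ld, f_next, n_frames)
            lift_x = prev_x if j == 0 else col["landing_x"][j - 1]
            if j > 0:
                prev_land = int(np.ceil(col["t_land"][j - 1] * rate))
                x[prev_land:f_sw] = lift_x
            t0, t1 = col["t_swing"][j], col["t_land"][j]
            land_x, l_pred, apex = (col["landing_x"][j], col["l_pred"][j],
                                    col["apex"][j])
            idx = np.arange(f_sw, f_ld)
            if idx.size:
                in_flight_mod = (c_mod[j] and np.isfinite(c_onset[j])
                                 and c_onset[j] > t0 + dt / 2)
                if in_flight_mod:
                    l_old = c_xplan[j] - lift_x
                    apex_planned = c_apexplan[j] if np.isfinite(c_apexplan[j]) \
                        else apex
                    t1p = c_tlandplan[j] if np.isfinite(c_tlandplan[j]) else t1
                    u_plan = np.clip((idx * dt - t0) / max(t1p - t0, dt),
                                     0.0, 1.0)
                    s_p = 0.5 * (1 - np.cos(np.pi * u_plan))
                    w_p = np.clip((u_plan - 0.5) / 0.5, 0.0, None) ** 2
                    xx = lift_x + s_p * l_pred + w_p * (l_old - l_pred)
                    zz = apex_planned * np.sin(np.pi * u_plan)
                    post = idx * dt >= c_onset[j]
                    if post.any():
                        i0 = np.argmax(post)
                        t_m = idx[i0] * dt
                        # the onset frame is the first frame that departs
                        # from the unmodified continuation, so the
                        # correction ramp is evaluated one frame in; it
                        # completes within ~20 ms
                        t_corr = min(max(t1 - t_m, 2 * dt), 0.016)
                        tt = idx[post] * dt - t_m + dt
                        ramp = np.sin(0.5 * np.pi * np.clip(tt / t_corr,
                                                            0.0, 1.0))
                        xx_post = xx[post] + (land_x - c_xplan[j]) * ramp
                        # a braking paw may stall but does not move backwards
                        xx[post] = np.maximum.accumulate(xx_post)
                        if land_x < c_xplan[j]:
                            # shorten: the paw is placed down -- height
                            # descends from the onset to landing
                            frac = np.clip((t1 - idx[post] * dt - dt)
                                           / max(t1 - t_m, 2 * dt), 0.0, 1.0)
                            zz[post] = zz[i0] * frac
                        else:
                            # lengthen: blend toward the apex profile of the
                            # extended swing (raised on cleared steps) with a
                            # fast ramp
                            z_tgt = apex * np.sin(np.pi * np.clip(
                                (idx[post] * dt - t0) / (t1 - t0), 0, 1))
                            ramp_z = np.sin(0.5 * np.pi * np.clip(
                                tt / min(t_corr, 0.008), 0.0, 1.0))
                            zz[post] = zz[post] + (z_tgt - zz[post]) * ramp_z
                    x[idx] = xx
                    z[idx] = np.maximum(zz, 0.0)
                else:
                    u = np.clip((idx * dt - t0) / max(t1 - t0, dt), 0.0, 1.0)
                    s = 0.5 * (1 - np.cos(np.pi * u))
                    w = np.clip((u - 0.5) / 0.5, 0.0, None) ** 2
                    x[idx] = lift_x + s * l_pred + w * (land_x - lift_x - l_pred)
                    z[idx] = apex * np.sin(np.pi * u)
            if f_ld < n_frames and j + 1 >= m:
                x[f_ld:] = land_x
            prev_x = land_x
            step_rows.append({
                "paw": paw, "cycle": int(col["cycle"][j]),
                "lift_frame": f_sw, "land_frame": f_ld,
                "lift_x_world": lift_x, "land_x_world": land_x,
                "length": land_x - lift_x, "speed": col["speed"][j],
                "apex": apex, "modified": bool(c_mod[j]),
                "crosses_obstacle": bool(c_cross[j]),
                "trial": int(col["trial"][j]),
            })
        world_x[paw] = x
        world_z[paw] = z

    # ---- other landmarks --------------------------------------------------
    body_angle = _ar1_frames_stable(n_frames, 0.995, 2.0, rng_noise)
    tail_z = 18.0 + _ar1_frames_stable(n_frames, 0.99, 1.5, rng_noise)
    nose_cam = _ar1_frames_stable(n_frames, 0.9, 0.5, rng_noise)

    cam = {}
    for paw in PAWS:
        cam[paw] = (world_x[paw] - displacement, world_z[paw])
    cam["nose"] = (nose_cam, np.full(n_frames, 12.0))
    cam["tail_base"] = (np.full(n_frames, -55.0), tail_z)
    cam["tail_mid"] = (np.full(n_frames, -80.0), tail_z + 2.0)

    obs_x_cam = np.full(n_frames, _OBSTACLE_HOME_X)
    obs_z = np.zeros(n_frames)
    for _, tr in truth.iterrows():
        f0 = int(round(tr["t_engage"] * rate))
        f1 = min(n_frames, int(np.searchsorted(
            displacement, tr["obstacle_x_world"] + 100.0)))
        obs_x_cam[f0:f1] = tr["obstacle_x_world"] - displacement[f0:f1]
        obs_z[f0:f1] = tr["obstacle_height"]
    cam["obstacle"] = (obs_x_cam, obs_z)

    lat = {}
    tan_a = np.tan(np.radians(body_angle))
    for lm in cam:
        if lm in ("tail_base", "tail_mid"):
            dist = 55.0 if lm == "tail_base" else 80.0
            lat[lm] = -dist * tan_a
        else:
            lat[lm] = np.full(n_frames, LATERAL[lm])

    sd = cfg.position_noise_sd
    views = {"top": {}, "bottom": {}}
    for lm in cam:
        xcam, zcam = cam[lm]
        conf = np.ones(n_frames)
        views["top"][lm] = np.column_stack([
            xcam + rng_noise.normal(0, sd, n_frames),
            zcam + rng_noise.normal(0, sd, n_frames), conf])
        views["bottom"][lm] = np.column_stack([
            xcam + rng_noise.normal(0, sd, n_frames),
            lat[lm] + rng_noise.normal(0, sd, n_frames), conf.copy()])

    raw = RawSession(frame_rate=rate, wheel_displacement=displacement,
                     views=views, trials=trials)
    gt = GroundTruth(trials=truth, steps=pd.DataFrame(step_rows),
                     step_law={"intercept": cfg.step_length_intercept,
                               "slope": cfg.step_length_slope,
                               "residual_sd": cfg.landing_noise_sd},
                     temperature=tau)
    return raw, gt
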