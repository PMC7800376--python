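"""Planted decision rule and trial-level decision-cohort simulation.

The generator's decision rule works on the *predicted landing distance*
``dpred``: where the forepaw in swing at whisker contact would land relative
to the obstacle if the step were not modified (negative = in front of the
obstacle).  The probability of lengthening the step is

    P(lengthen) = sigmoid((dpred - theta - c * height) / tau)

with threshold ``theta`` (mm), obstacle-height coefficient ``c`` (mm/mm) and
logistic temperature ``tau`` (mm).  ``tau`` is calibrated so that the Bayes
accuracy of the rule -- the accuracy of an observer who knows ``dpred`` and
the obstacle height exactly -- matches a target (0.73 by default) on the
distribution of trials that enter the decision analysis.

This module also provides a fast trial-level simulation of the eight contact
features.  It is the analytic counterpart of the frame-level session
generator in :mod:`obstride.sim.session`: both draw from the same gait and
contact model, but here each trial is a single row instead of a kinematic
trace, which makes Monte-Carlo calibration and large decision cohorts cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import GeneratorConfig
from ..errors import CalibrationError, ConfigurationError

__all__ = [
    "plant_decision",
    "lengthen_probability",
    "calibrate_decision_temperature",
    "generate_decision_trials",
    "generate_decision_cohort",
    "sample_control_steps",
    "resolve_temperature",
]


def lengthen_probability(predicted_landing, obstacle_height, config, tau=None):
    """Probability that the planted rule lengthens the step."""
    tau = config.decision_temperature if tau is None else tau
    if tau is None or tau <= 0:
        raise ConfigurationError("decision_temperature: must be positive")
    logit = (np.asarray(predicted_landing, float)
             - config.decision_threshold
             - config.decision_height_coefficient * np.asarray(obstacle_height, float))
    # numerically safe logistic
    return 0.5 * (1.0 + np.tanh(0.5 * logit / tau))


def plant_decision(predicted_landing, obstacle_height, config, rng, tau=None):
    """Draw the planted label for one trial (or an array of trials).

    Returns ``"lengthened"`` or ``"shortened"`` (arrays thereof for vector
    input).
    """
    p = lengthen_probability(predicted_landing, obstacle_height, config, tau)
    draw = rng.random(np.shape(p)) < p
    labels = np.where(draw, "lengthened", "shortened")
    return labels if labels.ndim else labels[()]


def _unmodified_probability(dpred, config, tau):
    """Probability that no modification is attempted.

    Steps predicted to land comfortably in front of the obstacle often need no
    adjustment; the probability decays to zero as the predicted landing
    approaches the obstacle.
    """
    theta = config.decision_threshold
    z = np.clip((np.asarray(dpred, float) - (theta - 5.0)) / tau, -60.0, 60.0)
    p = config.unmodified_max_probability / (1.0 + np.exp(z))
    return np.where(dpred < -4.0, p, 0.0)


def _draw_trial_features(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Draw the joint distribution of contact-time state for ``n`` trials.

    Mirrors the frame-level gait model: lift-off position follows from the
    regulated landing placement; swing progress at contact is uniform; the
    placement noise (step-length residual) accrues late in swing.
    """
    cfg = config
    v = rng.normal(cfg.mean_speed, cfg.speed_sd, n)
    v = np.clip(v, 0.15, None)
    height = rng.uniform(*cfg.obstacle_height_range, n)
    contact_noise = cfg.contact_noise_sd
    if not cfg.whiskers_present:
        contact_noise *= cfg.whiskerless_landing_noise_factor
    obstacle_x = (cfg.whisker_reach
                  + cfg.contact_speed_slope * (v - cfg.mean_speed)
                  + rng.normal(0.0, contact_noise, n))
    l_bar = cfg.predicted_step_length(v)
    landing = rng.normal(cfg.forepaw_landing_offset, cfg.placement_sd, n)
    lift_off = landing - cfg.duty_factor * l_bar
    dpred = lift_off + l_bar - obstacle_x

    u = rng.uniform(0.05, 0.95, n)            # swing phase at contact
    eps = rng.normal(0.0, cfg.landing_noise_sd, n)
    progress = 0.5 * (1.0 - np.cos(np.pi * u))
    late = np.clip((u - 0.5) / 0.5, 0.0, None) ** 2
    paw_x = lift_off + progress * l_bar + late * eps

    t_swing = (1.0 - cfg.duty_factor) * l_bar / (v * 1000.0)  # s
    z_amp = cfg.swing_height * l_bar / cfg.reference_step_length
    paw_z = z_amp * np.sin(np.pi * u) + rng.normal(0.0, 0.3, n)
    paw_vx = l_bar * np.pi / (2.0 * t_swing) * np.sin(np.pi * u)
    paw_vz = z_amp * np.pi / t_swing * np.cos(np.pi * u) + rng.normal(0.0, 10.0, n)
    body_angle = rng.normal(0.0, 2.0, n)

    feats = pd.DataFrame({
        "obstacle_x": obstacle_x,
        "obstacle_z": height,
        "paw_x": paw_x,
        "paw_z": paw_z,
        "paw_vx": paw_vx,
        "paw_vz": paw_vz,
        "wheel_velocity": v,
        "body_angle": body_angle,
    })
    return feats, dpred, eps, lift_off, u


def _draw_actual_landing(dpred, labels, unmodified, config, rng):
    """Actual landing distance (rel. obstacle) given the planted decision."""
    n = dpred.size
    out = np.empty(n)
    short = (labels == "shortened") & ~unmodified
    lon = (labels == "lengthened") & ~unmodified
    mu_s, sd_s = config.shorten_shift
    mu_l, sd_l = config.lengthen_shift
    delta_s = np.maximum(np.abs(rng.normal(mu_s, sd_s, n)), 3.0)
    delta_l = np.maximum(np.abs(rng.normal(mu_l, sd_l, n)), 3.0)
    out[short] = np.minimum(dpred[short] - delta_s[short], -6.0)
    out[lon] = dpred[lon] + delta_l[lon]
    wobble = np.clip(rng.normal(0.0, 1.0, n), -2.0, 2.0)
    out[unmodified] = dpred[unmodified] + wobble[unmodified]
    return out


def generate_decision_trials(config: GeneratorConfig, n_trials: int,
                             rng: np.random.Generator,
                             tau: float | None = None) -> pd.DataFrame:
    """Simulate ``n_trials`` obstacle trials at the trial level.

    Returns a DataFrame with the eight contact features, the ground-truth
    predicted landing distance (``true_dpred``), lift-off position,
    actual landing distance relative to the obstacle, the planted label, and
    an exclusion code (empty, ``BOTH_SWING`` or ``BOTH_STANCE``).
    """
    cfg = config
    tau = resolve_temperature(cfg) if tau is None else tau
    if not cfg.whiskers_present:
        tau = tau * cfg.whiskerless_temperature_factor
    feats, dpred, _, lift_off, u = _draw_trial_features(cfg, n_trials, rng)

    # forepaw duty 0.6 and antiphase forepaws: both in stance for a fraction
    # 2*(duty - 0.5) of the cycle; both in swing only through tracking noise.
    p_both_stance = max(0.0, 2.0 * (cfg.duty_factor - 0.5))
    roll = rng.random(n_trials)
    exclusion = np.full(n_trials, "", dtype=object)
    exclusion[roll < p_both_stance] = "BOTH_STANCE"
    exclusion[(roll >= p_both_stance) & (roll < p_both_stance + 0.02)] = "BOTH_SWING"

    labels = plant_decision(dpred, feats["obstacle_z"].to_numpy(), cfg, rng, tau)
    unmod = rng.random(n_trials) < _unmodified_probability(dpred, cfg, tau)
    labels = np.asarray(labels, dtype=object)
    labels[unmod] = "unmodified"
    actual = _draw_actual_landing(dpred, labels, unmod, cfg, rng)

    out = feats.copy()
    out["true_dpred"] = dpred
    out["lift_off_x"] = lift_off
    out["swing_phase"] = u
    out["actual_landing"] = actual
    out["true_label"] = labels
    out["exclusion"] = exclusion
    out["light"] = rng.random(n_trials) < cfg.light_on_probability
    return out


def sample_control_steps(config: GeneratorConfig, n_steps: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Draw (speed, step length) pairs from the planted step-length law."""
    v = np.clip(rng.normal(config.mean_speed, config.speed_sd, n_steps), 0.15, None)
    length = (config.predicted_step_length(v)
              + rng.normal(0.0, config.landing_noise_sd, n_steps))
    return pd.DataFrame({"wheel_velocity": v, "length": length})


def generate_decision_cohort(config: GeneratorConfig, n_mice: int,
                             sessions_per_mouse: int, trials_per_session: int,
                             seed: int, control_steps_per_session: int = 200,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of mice for decision modelling.

    Returns ``(trials, control_steps)``: per-trial rows tagged with
    ``mouse``/``session`` ids, and per-session control-step samples used to
    fit the landing models.  Per-mouse RNG streams are derived from ``seed``
    so mouse ``k`` is invariant to ``n_mice``.
    """
    tau = resolve_temperature(config)
    trial_frames, step_frames = [], []
    for m in range(n_mice):
        for s in range(sessions_per_mouse):
            rng = np.random.default_rng([seed, m, s])
            t = generate_decision_trials(config, trials_per_session, rng, tau)
            t.insert(0, "mouse", m)
            t.insert(1, "session", s)
            trial_frames.append(t)
            cs = sample_control_steps(config, control_steps_per_session, rng)
            cs.insert(0, "mouse", m)
            cs.insert(1, "session", s)
            step_frames.append(cs)
    return (pd.concat(trial_frames, ignore_index=True),
            pd.concat(step_frames, ignore_index=True))


def _bayes_accuracy(config: GeneratorConfig, tau: float, n: int,
                    rng: np.random.Generator) -> float:
    """Monte-Carlo Bayes accuracy of the planted rule on modelled trials."""
    feats, dpred, _, _, _ = _draw_trial_features(config, n, rng)
    p = lengthen_probability(dpred, feats["obstacle_z"].to_numpy(), config, tau)
    # drop trials that the pipeline excludes: both-paw ambiguity and
    # unmodified steps
    p_both_stance = max(0.0, 2.0 * (config.duty_factor - 0.5))
    keep = rng.random(n) >= p_both_stance + 0.02
    keep &= rng.random(n) >= _unmodified_probability(dpred, config, tau)
    p = p[keep]
    return float(np.mean(np.maximum(p, 1.0 - p)))


_TAU_UPPER = 1e4


def calibrate_decision_temperature(config: GeneratorConfig,
                                   target_accuracy: float | None = None,
                                   n_mc: int = 400_000,
                                   tol: float = 0.005,
                                   seed: int = 20210111) -> float:
    """Bisection on ``tau`` until the Monte-Carlo Bayes accuracy of the
    planted rule is within ``tol`` of ``target_accuracy``.

    Accuracy decreases monotonically in ``tau``.  A target of 0.5 (no
    information) is only reached as ``tau -> inf``; in that case the upper
    search bound is returned.  Targets above the accuracy achievable on the
    configured feature distribution raise :class:`CalibrationError`.
    """
    if target_accuracy is None:
        target_accuracy = config.decision_target_accuracy
    if not 0.5 < target_accuracy < 1.0:
        raise ConfigurationError("target_accuracy: must lie in (0.5, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = 1e-3, _TAU_UPPER
    acc_lo = _bayes_accuracy(config, lo, n_mc, np.random.default_rng(seed + 1))
    if acc_lo < target_accuracy - tol:
        raise CalibrationError(
            f"target accuracy {target_accuracy} unreachable; the configured "
            f"feature distribution supports at most ~{acc_lo:.3f}")
    acc_hi = _bayes_accuracy(config, hi, n_mc, np.random.default_rng(seed + 2))
    if acc_hi > target_accuracy:
        import warnings
        warnings.warn("target accuracy at or below the no-information limit; "
                      "returning the upper temperature bound", stacklevel=2)
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        acc = _bayes_accuracy(config, mid, n_mc, rng)
        if abs(acc - target_accuracy) <= tol * 0.5:
            return mid
        if acc > target_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_tau_cache: dict[tuple, float] = {}


def resolve_temperature(config: GeneratorConfig) -> float:
    """Return the configured temperature, calibrating (and caching) if unset."""
    if config.decision_temperature is not None:
        return config.decision_temperature
    key = (config.mean_speed, config.speed_sd, config.step_length_slope,
           config.step_length_intercept, config.landing_noise_sd,
           config.duty_factor, config.placement_sd,
           config.forepaw_landing_offset, config.whisker_reach,
           config.contact_speed_slope, config.contact_noise_sd,
           config.decision_threshold, config.decision_height_coefficient,
           config.decision_target_accuracy, config.unmodified_max_probability,
           config.obstacle_height_range)
    if key not in _tau_cache:
        _tau_cache[key] = calibrate_decision_temperature(config)
    return _tau_cache[key]
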