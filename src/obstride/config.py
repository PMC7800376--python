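"""Configuration dataclasses for the simulator and the analysis stages.

All positions are millimetres, speeds metres per second unless a field name
says otherwise.  Frames are 0-based at the session frame rate (250 Hz by
default, i.e. 4 ms per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ConfigurationError

#: canonical feature order of the decision model (ties in forward selection
#: are broken by this order)
DECISION_FEATURES = (
    "obstacle_x",
    "obstacle_z",
    "paw_x",
    "paw_z",
    "paw_vx",
    "paw_vz",
    "wheel_velocity",
    "body_angle",
)

PAWS = ("LF", "RF", "LH", "RH")
FOREPAWS = ("LF", "RF")
LANDMARKS = PAWS + ("tail_base", "tail_mid", "nose", "obstacle")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic locomotion / decision generator.

    The gait model plants the step-length law ``L = a + b*v + eps`` with
    ``eps ~ N(0, landing_noise_sd^2)``; with the default speed spread this
    yields a speed--step-length correlation of
    ``b*speed_sd / sqrt((b*speed_sd)^2 + landing_noise_sd^2) ~ 0.84`` and an
    in-sample landing-prediction MAE of ``landing_noise_sd*sqrt(2/pi) ~ 5.5 mm``.

    The planted decision rule lengthens the step of the forepaw in swing at
    whisker contact with probability
    ``sigmoid((dpred - theta - c*height) / tau)`` where ``dpred`` is the
    predicted landing distance relative to the obstacle (negative = in front),
    ``theta = decision_threshold``, ``c = decision_height_coefficient`` and
    ``tau = decision_temperature``.  ``tau`` defaults to ``None``, meaning it
    is calibrated so that the Bayes accuracy of the rule on the modelled trial
    distribution equals ``decision_target_accuracy``.
    """

    # sampling / session geometry
    frame_rate: float = 250.0          # Hz
    n_trials: int = 50                 # obstacle trials per session
    reward_distance: float = 5.4       # m of running per reward cycle

    # locomotion
    mean_speed: float = 0.55           # m/s
    speed_sd: float = 0.10             # m/s, across strides
    speed_ar: float = 0.3              # stride-to-stride AR(1) coefficient
    step_length_slope: float = 107.0   # mm per (m/s)
    step_length_intercept: float = -3.7  # mm
    landing_noise_sd: float = 6.9      # mm, residual SD about the length law
    duty_factor: float = 0.6           # fraction of stride in stance
    swing_height: float = 9.0          # mm, swing apex at the mean step length
    placement_sd: float = 12.0         # mm, stationary SD of landing position
    speed_modulation_ar: float = 0.9   # slow within-session speed drift (per stride)
    forepaw_landing_offset: float = -10.0  # mm, mean forepaw landing rel. nose
    hindpaw_landing_offset: float = -45.0  # mm, mean hindpaw landing rel. nose
    position_noise_sd: float = 0.25    # mm, per-frame tracking jitter

    # obstacle geometry (paper-stated trial structure)
    obstacle_height_range: tuple[float, float] = (4.0, 10.0)  # mm, uniform
    engage_distances: tuple[float, ...] = (0.9, 2.7, 4.5)     # m after reward
    engage_jitter: float = 0.1         # m, uniform +- jitter
    obstacle_start_distance: float = 0.31  # m ahead of the nose at engagement
    obstacle_start_jitter: float = 0.015   # m, uniform +- jitter
    obstacle_diameter: float = 3.175   # mm
    light_on_probability: float = 0.5

    # whisker contact
    whiskers_present: bool = True
    whisker_reach: float = 15.0        # mm anterior of nose at contact
    contact_speed_slope: float = 25.2  # mm per (m/s); with contact_noise_sd
    contact_noise_sd: float = 9.0      # produces corr(contact pos, speed) ~ 0.27

    # planted decision rule
    decision_threshold: float = -10.0  # mm (theta)
    decision_height_coefficient: float = 1.0  # mm shift of theta per mm height
    decision_temperature: float | None = None  # mm; None -> calibrated
    decision_target_accuracy: float = 0.73
    unmodified_max_probability: float = 0.35
    shorten_shift: tuple[float, float] = (10.0, 4.0)   # mm (mean, sd) of |delta|
    lengthen_shift: tuple[float, float] = (15.0, 5.0)  # mm (mean, sd) of |delta|
    obstacle_clearance: float = 5.0    # mm above the obstacle on cleared steps
    clearance_noise_sd: float = 1.5    # mm

    # whiskerless degradation
    whiskerless_temperature_factor: float = 3.0
    whiskerless_landing_noise_factor: float = 2.0

    # planted reaction
    planted_latency: float = 24.0      # ms between contact and onset

    # tracking-artifact injection rates (per frame per landmark per view)
    low_confidence_rate: float = 0.0
    jump_rate: float = 0.0
    jump_size: float = 30.0            # mm
    cross_view_rate: float = 0.0
    cross_view_size: float = 8.0       # mm
    gap_rate: float = 0.0
    gap_max_frames: int = 4

    seed: int | None = None

    def __post_init__(self) -> None:
        _require(self.frame_rate > 0, "frame_rate", "must be positive")
        _require(self.n_trials >= 0, "n_trials", "must be non-negative")
        _require(self.speed_sd >= 0, "speed_sd", "must be non-negative")
        _require(self.landing_noise_sd >= 0, "landing_noise_sd", "must be non-negative")
        _require(0 < self.duty_factor < 1, "duty_factor", "must lie in (0, 1)")
        lo, hi = self.obstacle_height_range
        _require(lo <= hi, "obstacle_height_range", "must be (low, high)")
        _require(0 <= self.light_on_probability <= 1, "light_on_probability",
                 "must lie in [0, 1]")
        if self.decision_temperature is not None:
            _require(self.decision_temperature > 0, "decision_temperature",
                     "must be positive")
        _require(0.5 < self.decision_target_accuracy < 1,
                 "decision_target_accuracy", "must lie in (0.5, 1)")
        _require(self.placement_sd**2 >= 0.5 * self.landing_noise_sd**2,
                 "placement_sd",
                 "must be at least landing_noise_sd/sqrt(2) for a stationary "
                 "placement process")
        _require(0 <= self.speed_modulation_ar < 1, "speed_modulation_ar",
                 "must lie in [0, 1)")
        for name in ("low_confidence_rate", "jump_rate", "cross_view_rate",
                     "gap_rate"):
            _require(0 <= getattr(self, name) <= 1, name, "must lie in [0, 1]")
        _require(self.whisker_reach > 0, "whisker_reach", "must be positive")
        _require(self.planted_latency >= 0, "planted_latency",
                 "must be non-negative")

    # derived quantities -------------------------------------------------
    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def reference_step_length(self) -> float:
        """Step length (mm) predicted at the mean speed."""
        return self.step_length_intercept + self.step_length_slope * self.mean_speed

    def predicted_step_length(self, speed):
        """a + b*speed in mm, the planted speed--length law without noise."""
        return self.step_length_intercept + self.step_length_slope * speed

    @property
    def placement_ar(self) -> float:
        """AR(1) coefficient of the body-relative landing placement.

        Landing placement (relative to the body) is a stationary AR(1) chain
        whose stride-to-stride increments are the step-length residuals, so
        the increment SD must equal ``landing_noise_sd`` while the marginal SD
        equals ``placement_sd``; this pins the autocorrelation at
        ``1 - landing_noise_sd^2 / (2 * placement_sd^2)``.
        """
        return 1.0 - self.landing_noise_sd**2 / (2.0 * self.placement_sd**2)

    def replace(self, **kw) -> "GeneratorConfig":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kw)
        return GeneratorConfig(**vals)


@dataclass
class QCConfig:
    """Thresholds for the tracking post-processing pipeline."""

    confidence_threshold: float = 0.99
    velocity_jump_threshold: float = 15.0  # mm between adjacent frames
    median_window: int = 3                 # frames
    cross_view_x_tolerance: float = 5.0    # mm
    max_masked_fraction: float = 0.5

    def __post_init__(self) -> None:
        _require(self.velocity_jump_threshold > 0, "velocity_jump_threshold",
                 "must be positive")
        _require(self.cross_view_x_tolerance > 0, "cross_view_x_tolerance",
                 "must be positive")
        _require(self.median_window % 2 == 1 and self.median_window >= 1,
                 "median_window", "must be odd and >= 1")


@dataclass
class StanceConfig:
    """Stance-detection thresholds."""

    velocity_tolerance: float = 0.2  # m/s around the wheel velocity
    height_tolerance: float = 5.0    # mm above the wheel surface
    debounce_ms: float = 20.0        # median-filter width

    def __post_init__(self) -> None:
        _require(self.velocity_tolerance > 0, "velocity_tolerance",
                 "must be positive")
        _require(self.height_tolerance > 0, "height_tolerance",
                 "must be positive")
        _require(self.debounce_ms >= 0, "debounce_ms", "must be non-negative")

    def debounce_frames(self, frame_rate: float) -> int:
        """Nearest odd number of frames spanning ``debounce_ms``."""
        n = max(1, round(self.debounce_ms * frame_rate / 1000.0))
        return n if n % 2 == 1 else n + 1


@dataclass
class ReactionConfig:
    """Parameters of the matched-control-step reaction-time estimator."""

    k: int = 40                       # matched control steps
    deviation_threshold: float = 2.5  # SD units
    sustain_frames: int = 2           # consecutive supra-threshold frames
    sd_floor: float = 0.1             # mm, floor on the family SD
    min_family_coverage: float = 0.5  # fraction of k that must cover a frame
    mid_swing_band: tuple[float, float] = (0.2, 0.8)  # "mid-swing" phase band

    def __post_init__(self) -> None:
        _require(self.k >= 2, "k", "must be >= 2")
        _require(self.deviation_threshold >= 0, "deviation_threshold",
                 "must be non-negative")
        _require(self.sustain_frames >= 1, "sustain_frames", "must be >= 1")
        _require(self.sd_floor > 0, "sd_floor", "must be positive")
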