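"""Injection of realistic tracking artifacts into a clean session.

Markerless pose estimation produces characteristic failure modes: frames the
network is unsure about (low confidence), single-frame jumps to a wrong
location, disagreement between the two camera views along the shared x axis,
and short stretches of missing data.  Each is injected at a configurable
per-frame rate; the injection log and the untouched clean views are kept on
the returned session so quality control can be scored against ground truth.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from ..config import GeneratorConfig
from ..errors import ConfigurationError
from .session import RawSession

__all__ = ["inject_tracking_artifacts"]


def inject_tracking_artifacts(clean: RawSession, config: GeneratorConfig,
                              rng: np.random.Generator) -> RawSession:
    """Return a corrupted copy of ``clean``; the input is not modified.

    Rates are per frame, per landmark, per view.  With all rates zero the
    output equals the input.  The returned session carries ``artifact_log``
    (one row per injected artifact) and ``clean_views`` (the pristine
    arrays) for recovery scoring.
    """
    for name in ("low_confidence_rate", "jump_rate", "cross_view_rate",
                 "gap_rate"):
        rate = getattr(config, name)
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name}: must lie in [0, 1]")
    n = clean.n_frames
    views = {v: {lm: arr.copy() for lm, arr in d.items()}
             for v, d in clean.views.items()}
    log = []

    for view, d in views.items():
        for lm, arr in d.items():
            # low-confidence frames
            m = rng.random(n) < config.low_confidence_rate
            if m.any():
                arr[m, 2] = rng.uniform(0.0, 0.989, m.sum())
                for f in np.nonzero(m)[0]:
                    log.append((view, lm, int(f), "low_confidence"))
            # single-frame jump outliers
            m = rng.random(n) < config.jump_rate
            m[0] = m[-1] = False
            if m.any():
                sign = rng.choice([-1.0, 1.0], m.sum())
                arr[m, 0] += sign * config.jump_size
                for f in np.nonzero(m)[0]:
                    log.append((view, lm, int(f), "jump"))
            # short gaps: confidence zeroed for a run of frames
            starts = np.nonzero(rng.random(n) < config.gap_rate)[0]
            for f in starts:
                ln = int(rng.integers(1, config.gap_max_frames + 1))
                arr[f:f + ln, 2] = 0.0
                for g in range(f, min(f + ln, n)):
                    log.append((view, lm, int(g), "gap"))

    # cross-view x disagreement: shift the top-view x only
    for lm, arr in views["top"].items():
        m = rng.random(n) < config.cross_view_rate
        if m.any():
            sign = rng.choice([-1.0, 1.0], m.sum())
            arr[m, 0] += sign * config.cross_view_size
            for f in np.nonzero(m)[0]:
                log.append(("top", lm, int(f), "cross_view"))

    out = RawSession(frame_rate=clean.frame_rate,
                     wheel_displacement=clean.wheel_displacement.copy(),
                     views=views, trials=clean.trials.copy(),
                     artifact_log=pd.DataFrame(
                         log, columns=["view", "landmark", "frame", "kind"]),
                     clean_views=copy.deepcopy(clean.views))
    return out
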