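"""Synthetic per-window first-contact probability streams.

The whisker-contact detector classifies sliding 10-frame windows into eleven
classes: "first contact is at relative position 1..10" or "first contact not
present".  This generator emits such streams around a known true contact
frame, with configurable label noise, so the downstream consensus vote can be
tested against ground truth without any video model.
"""

from __future__ import annotations

import numpy as np

from ..consensus import WINDOW_LEN, WindowPrediction
from ..errors import AnalysisError

__all__ = ["generate_window_probability_stream"]


def generate_window_probability_stream(true_contact_frame: int, n_frames: int,
                                       noise: float,
                                       rng: np.random.Generator
                                       ) -> list[WindowPrediction]:
    """Emit one prediction per stride-1 window of ``WINDOW_LEN`` frames.

    With ``noise == 0`` every window votes exactly: position ``c - start + 1``
    if the true frame ``c`` lies inside the window, otherwise the
    "not present" class.  With noise, a fraction of windows vote for a
    neighbouring frame (1 or 2 off) or a uniformly random class.
    """
    if not 0 <= true_contact_frame < n_frames:
        raise AnalysisError("true_contact_frame outside the stream")
    if not 0.0 <= noise <= 1.0:
        raise AnalysisError("noise must lie in [0, 1]")
    preds = []
    for start in range(0, n_frames - WINDOW_LEN + 1):
        rel = true_contact_frame - start + 1           # 1-based
        true_class = rel if 1 <= rel <= WINDOW_LEN else WINDOW_LEN + 1
        cls = true_class
        r = rng.random()
        if r < noise:
            kind = rng.random()
            if true_class <= WINDOW_LEN and kind < 0.6:
                cls = int(np.clip(true_class + rng.choice([-1, 1]), 1,
                                  WINDOW_LEN))
            elif true_class <= WINDOW_LEN and kind < 0.9:
                cls = int(np.clip(true_class + rng.choice([-2, 2]), 1,
                                  WINDOW_LEN))
            else:
                cls = int(rng.integers(1, WINDOW_LEN + 2))
        p = np.full(WINDOW_LEN + 1, 0.3 / WINDOW_LEN)
        p[cls - 1] = 0.7
        preds.append(WindowPrediction(start_frame=start, probabilities=p))
    return preds
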