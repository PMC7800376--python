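"""Sliding-window consensus for first-contact detection.

A per-window classifier reports, for every contiguous 10-frame window, which
relative position (1..10) holds the first whisker--obstacle contact, or that
the contact is not present in the window (class 11).  Each window casts one
hard vote for an absolute frame; the frame with the most votes wins, earliest
frame on ties.  A soft-vote variant accumulates the probability mass instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = ["WindowPrediction", "ConsensusResult", "consensus_first_contact",
           "evaluate_contact_error", "WINDOW_LEN"]

WINDOW_LEN = 10


@dataclass
class WindowPrediction:
    """An 11-class probability vector for one sliding window."""

    start_frame: int
    probabilities: np.ndarray  # length 11; positions 1..10, then "not present"

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if p.shape != (WINDOW_LEN + 1,):
            raise AnalysisError("probabilities must have length 11")
        if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise AnalysisError("probabilities must be non-negative and sum to 1")
        self.probabilities = p


@dataclass
class ConsensusResult:
    frame: int | None
    votes: dict            # absolute frame -> vote count (or mass)
    margin: float          # top votes minus runner-up (0 if single candidate)


def consensus_first_contact(stream: list[WindowPrediction],
                            soft: bool = False) -> ConsensusResult:
    """Combine per-window predictions into a single first-contact frame.

    Hard voting (default): each window votes for the frame at
    ``start_frame + argmax_class - 1`` unless the "not present" class wins,
    in which case it abstains.  Soft voting accumulates probability mass on
    each frame instead.  Ties resolve to the earliest frame.
    """
    votes: dict[int, float] = {}
    for wp in stream:
        if soft:
            for c in range(WINDOW_LEN):
                f = wp.start_frame + c
                votes[f] = votes.get(f, 0.0) + wp.probabilities[c]
        else:
            cls = int(np.argmax(wp.probabilities)) + 1
            if cls <= WINDOW_LEN:
                f = wp.start_frame + cls - 1
                votes[f] = votes.get(f, 0.0) + 1.0
    if not votes or max(votes.values()) <= 0:
        return ConsensusResult(frame=None, votes=votes, margin=0.0)
    top = max(votes.values())
    winner = min(f for f, v in votes.items() if v == top)
    others = [v for f, v in votes.items() if f != winner]
    margin = top - max(others) if others else top
    return ConsensusResult(frame=winner, votes=votes, margin=margin)


def evaluate_contact_error(predicted, true, frame_rate: float
                           ) -> tuple[float, float]:
    """Mean and SD of the timing error in ms; negative = early prediction."""
    predicted = np.asarray(predicted, float)
    true = np.asarray(true, float)
    if predicted.shape != true.shape:
        raise AnalysisError("predicted and true frame lists differ in length")
    err_ms = (predicted - true) * 1000.0 / frame_rate
    return float(np.mean(err_ms)), float(np.std(err_ms))


def stream_from_frame(df: pd.DataFrame) -> list[WindowPrediction]:
    """Read window predictions from a table (window_start, p1..p11)."""
    cols = [f"p{i}" for i in range(1, WINDOW_LEN + 2)]
    return [WindowPrediction(int(r["window_start"]),
                             r[cols].to_numpy(float))
            for _, r in df.iterrows()]
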