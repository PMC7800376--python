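"""Reaction-time estimation from kNN-matched control steps.

For the forepaw in swing at whisker contact, a family of k (default 40)
control steps is collected whose pre-contact trajectory -- aligned at swing
onset and compared over (x, z) displacement since lift-off -- is closest to
the trial's.  The family mean estimates what the paw would have done with no
obstacle; the per-frame deviation of the actual trajectory from that mean,
normalized by the family SD, crosses a 2.5 SD threshold at the reaction
onset.  Latency is the time from whisker contact to that crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ReactionConfig
from .errors import AnalysisError

__all__ = ["DeviationTrace", "match_control_steps", "deviation_trace",
           "onset_latency", "control_validation", "time_to_contact",
           "step_trajectory"]


def step_trajectory(x: np.ndarray, z: np.ndarray, lift: int, down: int,
                    y: np.ndarray | None = None,
                    horizon: int | None = None) -> np.ndarray:
    """Displacement-since-lift-off trajectory of one step, ``(T, C)``.

    Coordinates are (x, z) by default, optionally (x, y, z); x is referenced
    to the lift-off position so steps are comparable across the session.
    ``horizon`` fixes the trace length to that many frames from lift-off,
    following the paw through its landing into the subsequent stride (the
    deviation analysis is not confined to the swing in progress).
    """
    stop = down if horizon is None else min(lift + horizon, len(x))
    cols = [x[lift:stop] - x[lift]]
    if y is not None:
        cols.append(y[lift:stop] - y[lift])
    cols.append(z[lift:stop])
    return np.column_stack(cols)


def match_control_steps(query: np.ndarray, pool: list, cfg: ReactionConfig,
                        window: int | None = None) -> np.ndarray:
    """Indices of the ``cfg.k`` pool steps nearest to the query.

    Distance is the Euclidean norm over the aligned pre-contact window
    (``window`` frames from swing onset; defaults to the full query).  Pool
    steps shorter than the window are compared over their available frames
    with the mean per-frame distance, so step duration does not bias the
    ranking.  Ties resolve by pool order.
    """
    window = len(query) if window is None else int(window)
    window = min(window, len(query))
    if len(pool) < cfg.k:
        raise AnalysisError(f"pool has {len(pool)} steps, need >= {cfg.k}")
    q = np.asarray(query[:window], float)
    d = np.empty(len(pool))
    for i, s in enumerate(pool):
        w = min(window, len(s))
        if w == 0:
            d[i] = np.inf
            continue
        d[i] = np.sqrt(np.mean((np.asarray(s[:w], float) - q[:w]) ** 2))
    order = np.argsort(d, kind="stable")
    return order[:cfg.k]


@dataclass
class DeviationTrace:
    deviation: np.ndarray    # (T, C) actual - family mean
    family_sd: np.ndarray    # (T, C)
    normalized: np.ndarray   # (T,) RMS of deviation/SD across coordinates
    valid: np.ndarray        # (T,) frames with sufficient family coverage
    contact_idx: int         # frame index of whisker contact within the step
    truncated: bool = False


def deviation_trace(actual: np.ndarray, family: list, contact_idx: int,
                    cfg: ReactionConfig | None = None) -> DeviationTrace:
    """Deviation of the actual trajectory from the matched-family mean.

    All trajectories are aligned at swing onset.  Frames are valid while at
    least ``cfg.min_family_coverage * k_available`` family steps cover them;
    the family SD is floored at ``cfg.sd_floor`` mm.  ``normalized`` is the
    Euclidean norm of the per-coordinate deviations in SD units (for a
    single-coordinate trace a constant 1 SD offset gives exactly 1).
    """
    cfg = cfg or ReactionConfig()
    actual = np.asarray(actual, float)
    T, C = actual.shape
    k = len(family)
    counts = np.zeros(T, int)
    mean = np.zeros((T, C))
    m2 = np.zeros((T, C))
    for s in family:
        s = np.asarray(s, float)
        w = min(T, len(s))
        counts[:w] += 1
        delta = s[:w] - mean[:w]
        mean[:w] += delta / counts[:w, None]
        m2[:w] += delta * (s[:w] - mean[:w])
    need = max(2, int(np.ceil(cfg.min_family_coverage * k)))
    valid = counts >= need
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(m2 / np.maximum(counts[:, None] - 1, 1))
    sd = np.maximum(sd, cfg.sd_floor)
    dev = actual - mean
    norm = np.sqrt(np.sum((dev / sd) ** 2, axis=1))
    norm[~valid] = np.nan
    return DeviationTrace(deviation=dev, family_sd=sd, normalized=norm,
                          valid=valid, contact_idx=int(contact_idx),
                          truncated=not valid.all())


def onset_latency(trace: DeviationTrace, cfg: ReactionConfig | None = None,
                  frame_rate: float = 250.0) -> float | None:
    """Latency (ms) from contact to the first sustained threshold crossing.

    The normalized deviation must exceed ``cfg.deviation_threshold`` for
    ``cfg.sustain_frames`` consecutive valid frames starting at or after
    contact; returns ``None`` if the threshold is never crossed.  Raising the
    threshold can only delay (never advance) the onset.
    """
    cfg = cfg or ReactionConfig()
    norm = trace.normalized
    c = trace.contact_idx
    above = (norm > cfg.deviation_threshold) & trace.valid \
        if cfg.deviation_threshold > 0 else trace.valid.copy()
    for f in range(c, len(norm) - cfg.sustain_frames + 1):
        if above[f:f + cfg.sustain_frames].all():
            return (f - c) * 1000.0 / frame_rate
    return None


def control_validation(pool: list, cfg: ReactionConfig | None = None,
                       frame_rate: float = 250.0,
                       n_queries: int | None = None) -> dict:
    """Estimate the method's false-onset rate on unperturbed steps.

    Each query step is removed from the pool, matched against the remainder,
    and treated as a 'trial' with a nominal contact at mid-swing; any onset
    detected is spurious by construction.  Returns the false-onset rate and
    the distribution of post-'contact' deviation magnitudes.
    """
    cfg = cfg or ReactionConfig()
    if len(pool) < cfg.k + 1:
        raise AnalysisError("pool too small for leave-one-out validation")
    n_queries = len(pool) if n_queries is None else min(n_queries, len(pool))
    onsets, devs = [], []
    for i in range(n_queries):
        query = pool[i]
        rest = pool[:i] + pool[i + 1:]
        c_idx = len(query) // 2
        idx = match_control_steps(query, rest, cfg, window=c_idx)
        tr = deviation_trace(query, [rest[j] for j in idx], c_idx, cfg)
        lat = onset_latency(tr, cfg, frame_rate)
        onsets.append(lat is not None)
        post = tr.normalized[c_idx:][tr.valid[c_idx:]]
        if post.size:
            devs.append(float(np.nanmean(post)))
    return {"false_onset_rate": float(np.mean(onsets)),
            "mean_post_contact_deviation": float(np.mean(devs)) if devs
            else np.nan,
            "n_queries": n_queries}


def time_to_contact(paw_x: dict, contact_frame: int, obstacle_x: float,
                    frame_rate: float = 250.0, n_fit: int = 100
                    ) -> float | None:
    """Extrapolated time (ms) until the leading paw reaches the obstacle.

    Per frame the most anterior world x across all paws is taken; a least
    squares line over the ``n_fit`` frames preceding contact extrapolates
    when that position reaches ``obstacle_x``.  Returns ``None`` (flagged)
    when the fit is not approaching the obstacle.
    """
    traces = np.column_stack(list(paw_x.values()))
    anterior = traces.max(axis=1)
    if contact_frame < n_fit:
        raise AnalysisError(f"need {n_fit} frames before contact")
    seg = anterior[contact_frame - n_fit:contact_frame]
    t = np.arange(-n_fit, 0) / frame_rate        # s, 0 at contact
    slope, intercept = np.polyfit(t, seg, 1)     # mm/s, mm at contact
    if slope <= 0:
        return None
    ttc = (obstacle_x - intercept) / slope * 1000.0
    if not np.isfinite(ttc) or ttc < 0:
        return None
    return float(ttc)
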