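"""Dominance metric, segmentation of dominance periods, duration statistics.

The dominance metric ``M = (m1E - m2E) / (m1E + m2E)`` compares the
excitatory population rates of the two pools within small time bins.  A
dominance period opens at a sign change of ``M`` and qualifies once ``|M|``
stays above a threshold (default 0.4) continuously for a minimum duration
(default 100 ms); it ends at the next sign change.  Everything before the
first qualifying period is the initial transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .simulator import SimOutput

__all__ = [
    "DominanceSegment",
    "DominanceStats",
    "dominance_metric",
    "metric_series",
    "segment_dominance",
    "summarize",
    "fit_gamma",
    "pool_threshold_trace",
]


@dataclass
class DominanceSegment:
    pool: int          # 1 or 2
    t_start: float     # ms
    t_end: float       # ms
    is_transient: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class DominanceStats:
    durations_pool1: np.ndarray
    durations_pool2: np.ndarray
    predominance: Tuple[float, float]
    alternation_rate: float       # qualifying periods per ms
    n_segments: int
    n_switches: int               # transitions between qualifying periods
    total_time: float
    gamma_pool1: Optional[Tuple[float, float]] = None
    gamma_pool2: Optional[Tuple[float, float]] = None
    gamma_pooled: Optional[Tuple[float, float]] = None

    @property
    def durations_pooled(self) -> np.ndarray:
        return np.concatenate([self.durations_pool1, self.durations_pool2])


def dominance_metric(rate_E1, rate_E2):
    """``(m1E - m2E) / (m1E + m2E)`` in [-1, 1]; 0 when both rates vanish."""
    r1 = np.asarray(rate_E1, dtype=float)
    r2 = np.asarray(rate_E2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("firing rates must be nonnegative")
    tot = r1 + r2
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(tot > 0, (r1 - r2) / np.where(tot > 0, tot, 1.0), 0.0)
    if m.ndim == 0:
        return float(m)
    return m


def metric_series(sim: SimOutput) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin dominance metric from a simulation.

    Returns ``(bin_centers_ms, M, undecided)`` where ``undecided`` flags bins
    in which neither excitatory population fired.
    """
    r1 = sim.excitatory_rate_bins(1)
    r2 = sim.excitatory_rate_bins(2)
    m = dominance_metric(r1, r2)
    undecided = (r1 + r2) == 0
    centers = (np.arange(sim.n_bins) + 0.5) * sim.bin_ms
    return centers, np.atleast_1d(m), undecided


def segment_dominance(
    M_series: Sequence[float],
    bin_ms: float,
    threshold: float = 0.4,
    min_duration: float = 100.0,
    undecided: Optional[Sequence[bool]] = None,
) -> List[DominanceSegment]:
    """Segment a binned dominance-metric series into dominance periods.

    A candidate period opens at each sign change of ``M`` and spans until the
    next sign change.  It qualifies as a dominance segment if within it
    ``|M| > threshold`` holds continuously for at least ``min_duration``
    (undecided bins break a qualification streak).  The stretch before the
    first sign change, together with any later non-qualifying candidates,
    carries no dominance attribution; the interval before the first
    qualifying segment is returned as a transient segment.
    """
    M = np.asarray(M_series, dtype=float)
    if M.size == 0:
        raise ValueError("empty metric series")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if min_duration < bin_ms:
        raise ValueError("min_duration must be at least one bin")
    und = (np.zeros(M.size, dtype=bool) if undecided is None
           else np.asarray(undecided, dtype=bool))
    sign = np.sign(M).astype(int)
    sign[und] = 0
    min_bins = int(math.ceil(min_duration / bin_ms))

    # candidate boundaries: first bin whose sign is opposite to the sign of
    # the current candidate; zero bins extend the current candidate
    candidates = []  # (start_bin, end_bin_exclusive, pool_sign)
    cur_sign = 0
    cur_start = None
    n = M.size
    first_nonzero = np.flatnonzero(sign)
    if first_nonzero.size == 0:
        return []
    # the initial stretch, before any sign change, is never a candidate
    i0 = first_nonzero[0]
    cur_sign = sign[i0]
    for i in range(i0, n):
        if sign[i] != 0 and sign[i] != cur_sign:
            if cur_start is not None:
                candidates.append((cur_start, i, cur_sign))
            cur_sign = sign[i]
            cur_start = i
    if cur_start is not None:
        candidates.append((cur_start, n, cur_sign))

    def qualifies(a: int, b: int) -> bool:
        streak = 0
        for i in range(a, b):
            if not und[i] and abs(M[i]) > threshold:
                streak += 1
                if streak >= min_bins:
                    return True
            else:
                streak = 0
        return False

    segments: List[DominanceSegment] = []
    for a, b, s in candidates:
        if qualifies(a, b):
            segments.append(DominanceSegment(
                pool=1 if s > 0 else 2,
                t_start=a * bin_ms, t_end=b * bin_ms))
    if segments:
        t_first = segments[0].t_start
        if t_first > 0:
            pre = M[: int(round(t_first / bin_ms))]
            pool = 1 if pre.sum() >= 0 else 2
            segments.insert(0, DominanceSegment(
                pool=pool, t_start=0.0, t_end=t_first, is_transient=True))
    return segments


def summarize(segments: Sequence[DominanceSegment], total_time: float,
              fit: bool = False) -> DominanceStats:
    """Predominance, alternation rate and per-pool durations.

    The alternation rate counts qualifying dominance periods per unit time;
    transient and undecided intervals contribute no dominance time.
    """
    good = [s for s in segments if not s.is_transient]
    d1 = np.array([s.duration for s in good if s.pool == 1])
    d2 = np.array([s.duration for s in good if s.pool == 2])
    pred = (d1.sum() / total_time if total_time > 0 else 0.0,
            d2.sum() / total_time if total_time > 0 else 0.0)
    stats = DominanceStats(
        durations_pool1=d1, durations_pool2=d2, predominance=pred,
        alternation_rate=len(good) / total_time if total_time > 0 else 0.0,
        n_segments=len(good), n_switches=max(0, len(good) - 1),
        total_time=total_time)
    if fit:
        for attr, d in (("gamma_pool1", d1), ("gamma_pool2", d2),
                        ("gamma_pooled", np.concatenate([d1, d2]))):
            if d.size >= 2:
                setattr(stats, attr, fit_gamma(d))
    return stats


def fit_gamma(durations) -> Tuple[float, float]:
    """Maximum-likelihood gamma fit with location fixed at zero.

    Returns ``(shape, scale)`` with the scale in the units of the input.  A
    zero-variance sample is degenerate and returns ``(inf, 0.0)``.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 durations to fit")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if np.ptp(d) == 0:
        return (math.inf, 0.0)
    shape, _, scale = sps.gamma.fit(d, floc=0)
    return float(shape), float(scale)


def pool_threshold_trace(sim: SimOutput, pool: int
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Network-averaged firing threshold of one pool over time.

    Returns ``(sample_times_ms, mean_threshold)`` averaged over all neurons
    (excitatory and inhibitory) in the pool.
    """
    if pool not in (1, 2):
        raise ValueError("pool must be 1 or 2")
    N_E, N_I = sim.params.N_E, sim.params.N_I
    gE, gI = (0, 1) if pool == 1 else (2, 3)
    mean = (sim.th_trace[:, gE] * N_E + sim.th_trace[:, gI] * N_I) / (N_E + N_I)
    return sim.sample_times, mean
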