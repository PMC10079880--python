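"""Scripted experiment pipelines: rivalry runs, duration statistics,
stimulus-strength (Levelt) sweeps, adaptation ablations, inhibition scaling.

Every pipeline derives all randomness from one integer seed through
``numpy.random.SeedSequence`` spawning, records the seeds it used, and is
bit-reproducible from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dominance import (DominanceSegment, DominanceStats, metric_series,
                        pool_threshold_trace, segment_dominance, summarize)
from .network import NetworkRealization, build_network
from .params import ModelParams, RFParams
from .reconstruction import ReconstructionResult, reconstruct_run
from .simulator import SimOutput, simulate
from .stimuli import (StimulusImage, make_grating, make_scene_surrogate,
                      normalize_stimulus)

__all__ = [
    "RivalryRun", "SweepResult", "PooledDurations", "make_stimulus_pair",
    "run_rivalry", "segment_run", "multi_realization_durations",
    "levelt_sweep_asymmetric", "levelt_sweep_symmetric", "inhibition_sweep",
    "escape_release_report", "occupancy_predominance",
    "threshold_run_durations",
]

#: segmentation defaults: the 0.4 / 100 ms dominance rule on 50 ms bins
METRIC_BIN_MS = 50.0
DOMINANCE_THRESHOLD = 0.4
MIN_DOMINANCE_MS = 100.0


def _two_seeds(child: np.random.SeedSequence) -> Tuple[int, int]:
    a, b = child.generate_state(2)
    return int(a % (2**31)), int(b % (2**31))


def make_stimulus_pair(
    params: ModelParams,
    kind: str = "gratings",
    seed: Optional[int] = None,
) -> Tuple[StimulusImage, StimulusImage]:
    """Default monocular stimulus pair, normalized to the pool strengths.

    ``gratings``: a horizontal and a vertical square-wave grating.
    ``scenes``: two independent 1/f^2 scene surrogates.
    """
    side = params.side
    if kind == "gratings":
        raw1 = make_grating(side, "horizontal")
        raw2 = make_grating(side, "vertical")
    elif kind == "scenes":
        rng = np.random.default_rng(seed)
        raw1 = make_scene_surrogate(side, rng=rng)
        raw2 = make_scene_surrogate(side, rng=rng)
    else:
        raise ValueError("kind must be 'gratings' or 'scenes'")
    return (normalize_stimulus(raw1, params.m0_for_pool(1)),
            normalize_stimulus(raw2, params.m0_for_pool(2)))


@dataclass
class RivalryRun:
    params: ModelParams
    network: NetworkRealization
    stimuli: Tuple[StimulusImage, StimulusImage]
    sim: SimOutput
    segments: List[DominanceSegment]
    stats: DominanceStats
    reconstructions: Optional[List[ReconstructionResult]] = None
    seeds: Optional[Tuple[int, int]] = None


def segment_run(sim: SimOutput) -> Tuple[List[DominanceSegment], DominanceStats]:
    """Apply the dominance rule to a simulation and summarize."""
    _, M, und = metric_series(sim)
    segments = segment_dominance(M, sim.bin_ms, DOMINANCE_THRESHOLD,
                                 MIN_DOMINANCE_MS, undecided=und)
    stats = summarize(segments, sim.duration)
    return segments, stats


def run_rivalry(
    params: ModelParams,
    duration: float = 6000.0,
    seed: Optional[int] = None,
    stimulus_kind: str = "gratings",
    rf: Optional[RFParams] = None,
    reconstruct: bool = False,
    record_spikes: bool = False,
    sparsity_budget: Optional[int] = None,
    stimuli: Optional[Tuple[StimulusImage, StimulusImage]] = None,
) -> RivalryRun:
    """End-to-end rivalry pipeline.

    Build network -> normalize stimuli -> simulate -> segment -> summarize
    -> (optionally) reconstruct each dominance window's percept.
    """
    ss = np.random.SeedSequence(seed)
    net_child, sim_child, stim_child = ss.spawn(3)
    net_seed, _ = _two_seeds(net_child)
    sim_seed, _ = _two_seeds(sim_child)
    network = build_network(params, seed=net_seed, rf=rf)
    if stimuli is None:
        stim_seed, _ = _two_seeds(stim_child)
        stimuli = make_stimulus_pair(params, stimulus_kind, seed=stim_seed)
    sim = simulate(network, stimuli, params, duration, seed=sim_seed,
                   bin_ms=METRIC_BIN_MS, record_spikes=record_spikes)
    segments, stats = segment_run(sim)
    recons = None
    if reconstruct:
        recons = reconstruct_run(sim, network, segments, params,
                                 truths=stimuli,
                                 sparsity_budget=sparsity_budget)
    return RivalryRun(params=params, network=network, stimuli=stimuli,
                      sim=sim, segments=segments, stats=stats,
                      reconstructions=recons, seeds=(net_seed, sim_seed))


@dataclass
class PooledDurations:
    durations_pool1: np.ndarray
    durations_pool2: np.ndarray
    n_realizations: int
    duration_per_realization: float
    seeds: List[int]
    gamma_pool1: Tuple[float, float]
    gamma_pool2: Tuple[float, float]
    gamma_pooled: Tuple[float, float]
    skewness: float
    mean_ms: float

    @property
    def durations_pooled(self) -> np.ndarray:
        return np.concatenate([self.durations_pool1, self.durations_pool2])


def multi_realization_durations(
    params: ModelParams,
    n_realizations: int = 10,
    duration: float = 40000.0,
    seed: Optional[int] = None,
    stimulus_kind: str = "gratings",
) -> PooledDurations:
    """Pool non-transient dominance durations across network realizations.

    Emulates analyzing several individuals: each realization draws a fresh
    network, runs for ``duration`` ms and contributes its dominance
    durations; a gamma distribution is fitted per pool and pooled.
    """
    from .dominance import fit_gamma

    ss = np.random.SeedSequence(seed)
    d1, d2, seeds = [], [], []
    for child in ss.spawn(n_realizations):
        run_seed, _ = _two_seeds(child)
        seeds.append(run_seed)
        run = run_rivalry(params, duration=duration, seed=run_seed,
                          stimulus_kind=stimulus_kind)
        d1.append(run.stats.durations_pool1)
        d2.append(run.stats.durations_pool2)
    d1 = np.concatenate(d1)
    d2 = np.concatenate(d2)
    pooled = np.concatenate([d1, d2])
    return PooledDurations(
        durations_pool1=d1, durations_pool2=d2,
        n_realizations=n_realizations, duration_per_realization=duration,
        seeds=seeds,
        gamma_pool1=fit_gamma(d1), gamma_pool2=fit_gamma(d2),
        gamma_pooled=fit_gamma(pooled),
        skewness=float(sps.skew(pooled)), mean_ms=float(pooled.mean()))


@dataclass
class SweepResult:
    grid: List[float]
    table: pd.DataFrame
    stats: List[DominanceStats]
    seeds: List[int]
    duration: float


def occupancy_predominance(sim, threshold: float = DOMINANCE_THRESHOLD
                           ) -> Tuple[float, float]:
    """Fraction of time each pool dominates, attributed bin-by-bin.

    A bin counts toward pool k when the metric exceeds ``threshold`` in k's
    favor.  Unlike segment-based predominance this also attributes sustained
    dominance that never alternates (winner-take-all runs).
    """
    _, M, und = metric_series(sim)
    p1 = float(np.mean((M > threshold) & ~und))
    p2 = float(np.mean((M < -threshold) & ~und))
    return p1, p2


def threshold_run_durations(sim, threshold: float = DOMINANCE_THRESHOLD,
                            min_ms: float = MIN_DOMINANCE_MS):
    """Durations of maximal threshold-exceeding dominance stretches per pool.

    Complements the sign-change segmentation in sweeps: a winner-take-all
    run contributes one long stretch instead of none.
    """
    _, M, und = metric_series(sim)
    out = {1: [], 2: []}
    for pool, mask in ((1, (M > threshold) & ~und),
                       (2, (M < -threshold) & ~und)):
        padded = np.concatenate([[False], mask, [False]])
        d = np.diff(padded.astype(int))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        durs = (ends - starts) * sim.bin_ms
        out[pool] = durs[durs >= min_ms]
    return out[1], out[2]


def _sweep(params_list: Sequence[ModelParams], labels: Sequence[float],
           label_name: str, duration: float, seed: Optional[int],
           stimulus_kind: str = "gratings") -> SweepResult:
    ss = np.random.SeedSequence(seed)
    rows, stats_list, seeds = [], [], []
    for p, lab, child in zip(params_list, labels, ss.spawn(len(params_list))):
        run_seed, _ = _two_seeds(child)
        seeds.append(run_seed)
        run = run_rivalry(p, duration=duration, seed=run_seed,
                          stimulus_kind=stimulus_kind)
        st = run.stats
        stats_list.append(st)
        occ1, occ2 = occupancy_predominance(run.sim)
        r1, r2 = threshold_run_durations(run.sim)
        rows.append({
            label_name: lab,
            "predominance_1": occ1,
            "predominance_2": occ2,
            "segment_predominance_1": st.predominance[0],
            "segment_predominance_2": st.predominance[1],
            "mean_duration_1": (float(st.durations_pool1.mean())
                                if st.durations_pool1.size else np.nan),
            "mean_duration_2": (float(st.durations_pool2.mean())
                                if st.durations_pool2.size else np.nan),
            "mean_duration": (float(st.durations_pooled.mean())
                              if st.durations_pooled.size else np.nan),
            "alternation_rate": st.alternation_rate,
            "n_segments": st.n_segments,
            "run_mean_duration_1": (float(np.mean(r1)) if len(r1) else 0.0),
            "run_mean_duration_2": (float(np.mean(r2)) if len(r2) else 0.0),
        })
    return SweepResult(grid=list(labels), table=pd.DataFrame(rows),
                       stats=stats_list, seeds=seeds, duration=duration)


def levelt_sweep_asymmetric(
    params: ModelParams,
    m0_1_grid: Sequence[float],
    m0_2_fixed: float = 1.0,
    duration: float = 40000.0,
    seed: Optional[int] = None,
) -> SweepResult:
    """Vary pool 1's stimulus strength with pool 2 fixed (laws I-III)."""
    grid = [float(x) for x in m0_1_grid]
    plist = [params.replace(m0=x, m0_2=float(m0_2_fixed)) for x in grid]
    return _sweep(plist, grid, "m0_1", duration, seed)


def levelt_sweep_symmetric(
    params: ModelParams,
    m0_grid: Sequence[float],
    duration: float = 40000.0,
    seed: Optional[int] = None,
) -> SweepResult:
    """Vary both stimulus strengths together (law IV)."""
    grid = [float(x) for x in m0_grid]
    plist = [params.replace(m0=x, m0_2=x) for x in grid]
    return _sweep(plist, grid, "m0", duration, seed)


def inhibition_sweep(
    params: ModelParams,
    S_I_grid: Sequence[float],
    duration: float = 40000.0,
    seed: Optional[int] = None,
) -> SweepResult:
    """Scale all intra-pool inhibitory strengths by S_I and record durations.

    Reduced inhibition (S_I < 1) emulates the weakened GABA signaling
    hypothesized for autism; the scaling leaves the balance-condition
    quotient |R_EI|/|R_II| unchanged.
    """
    grid = [float(x) for x in S_I_grid]
    if any(not (0 < x <= 1) for x in grid):
        raise ValueError("S_I grid must lie in (0, 1]")
    plist = [params.replace(S_I=x) for x in grid]
    return _sweep(plist, grid, "S_I", duration, seed)


def escape_release_report(
    params: ModelParams,
    m0_values: Sequence[float] = (0.25, 1.0),
    duration: float = 20000.0,
    seed: Optional[int] = None,
) -> Dict[float, dict]:
    """Threshold-trajectory diagnostics contrasting stimulus strengths.

    For each stimulus strength: pool-averaged threshold traces, dominance
    statistics, and the mean downward threshold speed of the suppressed pool
    (steep decay signals the escape mechanism; shallow decay the release
    mechanism).
    """
    ss = np.random.SeedSequence(seed)
    out: Dict[float, dict] = {}
    for m0, child in zip(m0_values, ss.spawn(len(list(m0_values)))):
        run_seed, _ = _two_seeds(child)
        p = params.replace(m0=float(m0), m0_2=float(m0))
        run = run_rivalry(p, duration=duration, seed=run_seed)
        times, tr1 = pool_threshold_trace(run.sim, 1)
        _, tr2 = pool_threshold_trace(run.sim, 2)
        decay = _suppressed_decay(times, (tr1, tr2), run.segments)
        out[float(m0)] = {
            "times": times, "trace_pool1": tr1, "trace_pool2": tr2,
            "stats": run.stats, "suppressed_decay_per_ms": decay,
            "mean_duration": (float(run.stats.durations_pooled.mean())
                              if run.stats.durations_pooled.size else np.nan),
            "seed": run_seed,
        }
    return out


def _suppressed_decay(times, traces, segments) -> float:
    """Mean -d(theta_bar)/dt of the suppressed pool over dominance windows."""
    slopes = []
    for seg in segments:
        if seg.is_transient:
            continue
        suppressed = traces[1] if seg.pool == 1 else traces[0]
        mask = (times >= seg.t_start) & (times <= seg.t_end)
        if mask.sum() < 3:
            continue
        t = times[mask]
        y = suppressed[mask]
        slope = np.polyfit(t, y, 1)[0]
        slopes.append(-slope)
    return float(np.mean(slopes)) if slopes else float("nan")
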