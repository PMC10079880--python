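"""Forward-Euler integration of the two-pool pulse-coupled network.

Dynamics per neuron: between spikes ``dv/dt = -g_L (v - V_Re) + I_ff`` with
the constant feedforward current ``I_ff = (F p)_i``; a presynaptic spike adds
the corresponding connectivity entry to the postsynaptic voltage at the start
of the next integration step.  On crossing the dynamic threshold the neuron
spikes, its voltage resets to ``V_Re`` and its threshold jumps by ``phi``
(subject to the adaptation mode); between spikes the threshold relaxes to the
non-adapted value ``theta_k`` at rate ``lambda``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from ._kernels import run_network, accumulate_ei
from .network import NetworkRealization
from .params import ModelParams
from .stimuli import StimulusImage

__all__ = ["SimOutput", "simulate", "population_rates", "window_statistics",
           "ei_input_ratios"]

#: group ids: 0 = pool-1 E, 1 = pool-1 I, 2 = pool-2 E, 3 = pool-2 I
GROUP_LABELS = ("pool1_E", "pool1_I", "pool2_E", "pool2_I")


@dataclass
class SimOutput:
    """Spike counts, sampled thresholds and running state accumulators.

    Per-neuron spike counts and running voltage/threshold sums are kept in
    uniform stats bins of width ``bin_ms`` (window means are assembled from
    these bins); population-averaged threshold traces are sampled every
    ``sample_ms``.  Raw spikes are stored only when requested.
    """

    params: ModelParams
    duration: float
    dt: float
    bin_ms: float
    sample_ms: float
    seed: Optional[int]
    counts: np.ndarray          # (2M, n_bins) spike counts
    vsum: np.ndarray            # (2M, n_bins) running voltage sums
    thsum: np.ndarray           # (2M, n_bins) running threshold sums
    resetsum: np.ndarray        # (2M, n_bins) voltage removed by resets
    clampsum: np.ndarray        # (2M, n_bins) voltage added by the V_floor clamp
    nsamp: np.ndarray           # (n_bins,) samples per bin
    th_trace: np.ndarray        # (n_samples, 4) group-mean thresholds
    acc_exc: np.ndarray         # (2M,) cumulative excitatory input (incl. ff)
    acc_inh: np.ndarray         # (2M,) cumulative inhibitory input (<= 0)
    spike_times: Optional[np.ndarray] = None
    spike_ids: Optional[np.ndarray] = None
    n_spikes_total: int = 0
    spikes_truncated: bool = False
    th_full: Optional[np.ndarray] = None   # (n_samples, 2M) when recorded

    @property
    def M(self) -> int:
        return self.params.M

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_ms

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(self.th_trace.shape[0]) * self.sample_ms

    def pool_slice(self, pool: int, population: Optional[str] = None) -> slice:
        """Index slice for a pool (1 or 2), optionally one population."""
        M, N_E = self.M, self.params.N_E
        base = 0 if pool == 1 else M
        if population is None:
            return slice(base, base + M)
        if population == "E":
            return slice(base, base + N_E)
        if population == "I":
            return slice(base + N_E, base + M)
        raise ValueError("population must be 'E', 'I' or None")

    def excitatory_rate_bins(self, pool: int) -> np.ndarray:
        """Population-averaged excitatory rate per stats bin (spikes/ms)."""
        sl = self.pool_slice(pool, "E")
        return self.counts[sl].sum(axis=0) / (self.params.N_E * self.bin_ms)


def _initial_voltages(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform in [V_Re, theta_k) per population, both pools."""
    M, N_E = params.M, params.N_E
    v = np.empty(2 * M)
    for z in range(2):
        off = z * M
        v[off:off + N_E] = rng.uniform(params.V_Re, params.theta_E, N_E)
        v[off + N_E:off + M] = rng.uniform(params.V_Re, params.theta_I, M - N_E)
    return v


def simulate(
    network: NetworkRealization,
    stimuli: Sequence[StimulusImage],
    params: ModelParams,
    duration: float,
    seed: Optional[int] = None,
    bin_ms: float = 50.0,
    sample_ms: float = 1.0,
    record_spikes: bool = False,
    record_full_thresholds: bool = False,
    max_spike_rate: float = 2.0,
) -> SimOutput:
    """Integrate both pools for ``duration`` ms and collect recordings.

    ``stimuli`` is the pair of monocular images (pool 1, pool 2), normalized
    to their configured mean values.  ``max_spike_rate`` (spikes/ms/neuron)
    sizes the raw-spike buffer when ``record_spikes`` is on; spike *counts*
    remain exact even if the raw buffer fills.
    """
    if duration < params.dt:
        raise ValueError("duration must be at least one integration step")
    p1, p2 = stimuli
    for z, img in ((1, p1), (2, p2)):
        target = params.m0_for_pool(z)
        if abs(img.mean_value - target) > 1e-9:
            warnings.warn(
                f"stimulus for pool {z} has mean {img.mean_value:.6g}, "
                f"expected m0={target:.6g}; did you normalize_stimulus()?")
    M = params.M
    T = 2 * M
    rng = np.random.default_rng(seed)

    W = sp.bmat(
        [[network.R1, network.C2], [network.C1, network.R2]], format="csc")
    indptr = W.indptr.astype(np.int64)
    indices = W.indices.astype(np.int32)
    data = W.data.astype(np.float64)

    Iff = np.concatenate(
        [np.asarray(network.F1 @ p1.vector).ravel(),
         np.asarray(network.F2 @ p2.vector).ravel()])

    N_E = params.N_E
    th0 = np.empty(T)
    for z in range(2):
        off = z * M
        th0[off:off + N_E] = params.theta_E
        th0[off + N_E:off + M] = params.theta_I
    th = th0.copy()
    v = _initial_voltages(params, rng)

    adapt = np.zeros(T, dtype=np.uint8)
    if params.adaptation_mode == "both":
        adapt[:] = 1
    elif params.adaptation_mode == "excitatory_only":
        for z in range(2):
            adapt[z * M:z * M + N_E] = 1

    gid = np.empty(T, dtype=np.int32)
    for z in range(2):
        gid[z * M:z * M + N_E] = 2 * z
        gid[z * M + N_E:(z + 1) * M] = 2 * z + 1
    gcount = np.bincount(gid, minlength=4).astype(np.int64)

    n_steps = int(round(duration / params.dt))
    bin_steps = max(1, int(round(bin_ms / params.dt)))
    n_bins = int(np.ceil(n_steps / bin_steps))
    sample_every = max(1, int(round(sample_ms / params.dt)))
    n_samples = n_steps // sample_every + 1

    counts = np.zeros((T, n_bins), dtype=np.int64)
    vsum = np.zeros((T, n_bins))
    thsum = np.zeros((T, n_bins))
    resetsum = np.zeros((T, n_bins))
    clampsum = np.zeros((T, n_bins))
    nsamp = np.zeros(n_bins, dtype=np.int64)
    th_trace = np.zeros((n_samples, 4))
    th_full = (np.zeros((n_samples, T)) if record_full_thresholds
               else np.zeros((1, 1)))
    if record_spikes:
        cap = int(T * duration * max_spike_rate)
        spike_t = np.empty(cap)
        spike_i = np.empty(cap, dtype=np.int32)
    else:
        spike_t = np.empty(0)
        spike_i = np.empty(0, dtype=np.int32)

    n_rec, n_total = run_network(
        n_steps, params.dt, params.g_L, params.V_Re, params.V_floor,
        params.lambda_adapt,
        params.phi, v, th, th0, adapt, Iff, indptr, indices, data,
        bin_steps, counts, vsum, thsum, resetsum, clampsum, nsamp,
        sample_every, gid, gcount,
        th_trace, record_full_thresholds, th_full, record_spikes,
        spike_t, spike_i)

    if not np.isfinite(v).all():
        raise FloatingPointError(
            "non-finite voltages encountered; reduce dt or check parameters")

    acc_exc = np.zeros(T)
    acc_inh = np.zeros(T)
    accumulate_ei(indptr, indices, data, counts.sum(axis=1), acc_exc, acc_inh)
    acc_exc += Iff * duration  # constant feedforward drive is excitatory

    return SimOutput(
        params=params, duration=n_steps * params.dt, dt=params.dt,
        bin_ms=bin_steps * params.dt, sample_ms=sample_every * params.dt,
        seed=seed, counts=counts, vsum=vsum, thsum=thsum,
        resetsum=resetsum, clampsum=clampsum, nsamp=nsamp,
        th_trace=th_trace, acc_exc=acc_exc, acc_inh=acc_inh,
        spike_times=spike_t[:n_rec] if record_spikes else None,
        spike_ids=spike_i[:n_rec] if record_spikes else None,
        n_spikes_total=int(n_total),
        spikes_truncated=bool(record_spikes and n_rec < n_total),
        th_full=th_full if record_full_thresholds else None)


def population_rates(sim: SimOutput, bin_width: float):
    """Binned population rates (spikes/ms per neuron) for the four groups.

    Returns ``(bin_centers, rates)`` with ``rates`` of shape (4, n_bins) in
    the order pool1-E, pool1-I, pool2-E, pool2-I.  ``bin_width`` must be a
    multiple of the recording bin width.
    """
    if bin_width < sim.dt:
        raise ValueError("bin_width must be at least dt")
    k = int(round(bin_width / sim.bin_ms))
    if k < 1 or abs(k * sim.bin_ms - bin_width) > 1e-9:
        raise ValueError(
            f"bin_width must be a multiple of the recording bin "
            f"({sim.bin_ms} ms)")
    nb = sim.n_bins // k
    out = np.empty((4, nb))
    sizes = (sim.params.N_E, sim.params.N_I, sim.params.N_E, sim.params.N_I)
    for g, pop in enumerate((("E", 1), ("I", 1), ("E", 2), ("I", 2))):
        popname, pool = pop
        sl = sim.pool_slice(pool, popname)
        c = sim.counts[sl].sum(axis=0)[:nb * k].reshape(nb, k).sum(axis=1)
        out[g] = c / (sizes[g] * k * sim.bin_ms)
    centers = (np.arange(nb) + 0.5) * k * sim.bin_ms
    return centers, out


@dataclass
class WindowStats:
    """Per-neuron time-averaged statistics over one analysis window.

    ``rate`` is in spikes/ms; ``reset_rate`` and ``clamp_rate`` are the mean
    voltage removed per ms by spike resets and added per ms by the lower
    voltage bound (both network observables used by the input-output map).
    Iterating yields (rate, vmean, thmean) for backward-compatible
    unpacking.
    """

    rate: np.ndarray
    vmean: np.ndarray
    thmean: np.ndarray
    reset_rate: np.ndarray
    clamp_rate: np.ndarray
    t_start: float = 0.0
    t_end: float = 0.0

    def __iter__(self):
        return iter((self.rate, self.vmean, self.thmean))


def window_statistics(sim: SimOutput, t_start: float, t_end: float
                      ) -> WindowStats:
    """Per-neuron mean rate, voltage, threshold and flux rates over a window.

    The window is snapped to recording-bin edges.  Rates are in spikes/ms.
    """
    if t_end - t_start < 10 * sim.dt:
        raise ValueError("window too short (need at least 10 dt)")
    b0 = int(round(t_start / sim.bin_ms))
    b1 = int(round(t_end / sim.bin_ms))
    b0 = max(0, b0)
    b1 = min(sim.n_bins, b1)
    if b1 <= b0:
        raise ValueError("empty window after snapping to bin edges")
    span = (b1 - b0) * sim.bin_ms
    rate = sim.counts[:, b0:b1].sum(axis=1) / span
    ns = sim.nsamp[b0:b1].sum()
    vmean = sim.vsum[:, b0:b1].sum(axis=1) / ns
    thmean = sim.thsum[:, b0:b1].sum(axis=1) / ns
    reset_rate = sim.resetsum[:, b0:b1].sum(axis=1) / span
    clamp_rate = sim.clampsum[:, b0:b1].sum(axis=1) / span
    return WindowStats(rate=rate, vmean=vmean, thmean=thmean,
                       reset_rate=reset_rate, clamp_rate=clamp_rate,
                       t_start=b0 * sim.bin_ms, t_end=b1 * sim.bin_ms)


def ei_input_ratios(sim: SimOutput) -> Tuple[np.ndarray, int]:
    """Per-neuron ratio of cumulative excitatory to inhibitory input.

    Neurons with zero inhibitory input are excluded; returns
    ``(ratios, n_excluded)``.  Ratios are negative, with balance showing a
    histogram mode near -1.
    """
    mask = sim.acc_inh < 0
    ratios = sim.acc_exc[mask] / sim.acc_inh[mask]
    return ratios, int((~mask).sum())
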