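# Methods

## Model

Two pools of pulse-coupled leaky integrate-and-fire neurons represent two
ocular-dominance columns. Each pool holds `N_E` excitatory and `N_I`
inhibitory neurons (default 1000 + 1000). The voltage of neuron *i* obeys

    dv/dt = -g_L (v - V_Re) + I_ff,i + sum over presynaptic spikes of J_ij δ(t - t_spike)

between threshold crossings; on crossing its dynamic threshold θ_i the
neuron emits a spike, resets to `V_Re`, and θ_i jumps by `phi`
(spike-frequency adaptation); between spikes the threshold relaxes to the
population value θ_k at rate `lambda`. Voltages are non-dimensionalized:
`V_Re = 0`, θ_E = 1, θ_I = 0.8, and the leak `g_L = 0.05 /ms` corresponds to
a 20 ms membrane time constant.

**Connectivity.** All connections are independent Bernoulli draws. Within a
pool, an entry with presynaptic population *l* is present with probability
`K / N_l` and has weight `R_kl / sqrt(K)` (excitatory weights positive,
inhibitory negative, self-connections excluded). Between pools, only
excitatory-to-inhibitory connections exist, present with probability
`K / N_E` and weight `C_IE / sqrt(K)`. The feedforward matrix maps the `n`
stimulus pixels (default `n = 10 N_E`, a 10:1 sensory compression) to
downstream neurons, each entry present with probability `K / n` and weight
`f_k / sqrt(K)`, so a stimulus with mean pixel value `m0` delivers an
expected drive of `sqrt(K) f_k m0`. The `sqrt(K)` scaling is the standard
balanced-network normalization: the mean excitatory and inhibitory inputs
are each large (order `sqrt(K)` relative to threshold) and cancel, leaving
order-one fluctuations that drive irregular spiking. The feedforward
Bernoulli probability `K / n` (rather than `K / N_l`) preserves the
mean-in-degree-K interpretation; only the mean drive is constrained by the
coarse-grained theory.

**Lower voltage bound.** Inhibitory impulses cannot drive the voltage below
`V_floor = -2/3`, the inhibitory reversal potential in the standard
normalization (rest 0 and threshold 1 map -70 mV and -55 mV, so -80 mV maps
to -2/3). This bound is essential to the competition dynamics: without it,
suppressed-pool excitatory neurons hyperpolarize tens of threshold units
below threshold and no physiological adaptation strength can ever re-ignite
them, so the first dominant pool wins forever. With the bound at -2/3 the
model exhibits exactly the intended phenomenology — irregular alternations
with adaptation on, winner-take-all with adaptation off, and persistence of
alternations when only excitatory neurons adapt. The value is pinned by
those qualitative constraints, not fitted: a bound at 0 switches too fast
and too regularly, a bound at -1 or deeper freezes permanently.

**Receptive-field feedforward variant.** Each downstream neuron may instead
sample pixels through a Gaussian receptive field: row *i* is assigned a
distinct uniformly random center on the pixel grid and samples pixel *j*
with probability `rho * exp(-d²/(2 sigma²))` (defaults `rho = 0.92`,
`sigma = 2.2` pixels, about 28 connections per neuron on a 100x100 grid).

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `R_EE, R_IE` | 1, 1 | — | excitatory coupling strengths |
| `R_EI, R_II` | -2, -1.8 | — | inhibitory coupling strengths |
| `C_IE` | 1 | — | cross-pool E→I strength |
| `N_E, N_I` | 1000, 1000 | — | neurons per population per pool |
| `K` | 40 | — | mean in-degree per population |
| `f_E, f_I` | 1, 0.8 | — | feedforward scaling per population |
| `m0` | 0.5 | — | stimulus strength (mean pixel value) |
| `theta_E, theta_I` | 1, 0.8 | — | non-adapted thresholds |
| `g_L` | 0.05 | 1/ms | leak rate (20 ms membrane constant) |
| `lambda` | 0.00625 | 1/ms | threshold decay (160 ms) |
| `phi` | 0.005 | — | threshold jump per spike |
| `V_floor` | -2/3 | — | lower voltage bound |
| `S_I` | 1 | — | inhibition scaling (multiplies R_EI, R_II) |
| `dt` | 0.1 | ms | integration step |

The couplings satisfy the balance ordering
`f_E/f_I > |R_EI|/|R_II| > R_EE/R_IE` (1.25 > 1.11 > 1), which guarantees
positive finite population rates in the large-network limit; the balanced
rates are `m_E = m_I = m0` in normalized units at the default couplings, and
the simulated gain curve is linear in `m0` with nearly equal E and I rates.
`lambda` and `phi` are interpreted in 1/ms and per-spike units respectively;
halving `dt` changes single-pool population rates by under 2%.

## Integration and recording

Forward Euler with `dt = 0.1 ms`. Spikes fired during a step are delivered
to postsynaptic voltages at the start of the next step, which makes the
within-step update order irrelevant and runs reproducible bit-for-bit from
the seed. One reset per step; threshold crossings are resolved at step
boundaries. Initial voltages are uniform in `[V_Re, theta_k)` to
desynchronize startup; initial thresholds sit at θ_k.

Per-neuron spike counts, and running sums of voltage, threshold, reset flux
(voltage removed by resets) and clamp flux (voltage injected by the lower
bound) are accumulated into 50 ms bins, with voltage/threshold sampled every
1 ms; window averages over any bin-aligned interval are assembled from these
bins. Population-mean threshold traces are kept at 1 ms resolution. Raw
spike times are recorded only on request (unit tests, raster-style
diagnostics); 40 s production runs would otherwise store ~5 x 10^7 spikes.

## Dominance metric and segmentation

The metric `M = (m1E - m2E) / (m1E + m2E)` compares the two excitatory
populations' rates in 50 ms bins (both silent → 0, flagged undecided). A
candidate dominance period opens at a sign change of `M` and ends at the
next sign change; it qualifies if `|M| > 0.4` holds for at least 100 ms of
consecutive bins within the candidate (undecided bins break the streak).
The stretch before the first sign change is the initial transient and is
excluded from duration statistics. Gamma fits to dominance durations use
maximum likelihood with the location pinned at zero; a zero-variance sample
returns an infinite shape rather than raising.

Because a winner-take-all run contains no sign change, sweep summaries also
report bin-wise occupancy predominance (fraction of bins with `|M| > 0.4` in
a pool's favor) and threshold-stretch durations (maximal runs of
threshold-exceeding bins), which attribute sustained non-alternating
dominance sensibly.

## Input-output map and percept reconstruction

Time-averaging the voltage equation over a dominance window gives, per
neuron of the dominant pool,

    g_L (v̄ - V_Re) = F p + R m_own + C m_other - (reset flux) + (clamp flux)

up to the boundary term `(v(T) - v(0))/T`. All right-hand quantities except
`F p` are network observables measured within the window: per-neuron rates
`m` (spikes/ms), mean voltages, and the reset and clamp flux rates. Solving
for `F p` yields an underdetermined linear system for the unknown stimulus
`p` (2000 equations, 10000 pixels) whose solution is recovered by orthogonal
matching pursuit over the composite operator `F ∘ idct2` (orthonormal 2-D
DCT-II dictionary), exploiting the stimuli's frequency-domain sparsity.
Default sparsity budget is rows/4 (500 atoms) with relative residual
tolerance 1e-6; atoms are selected by maximal correlation and coefficients
refit by least squares via an incrementally updated Cholesky factor. An
equality-constrained l1 (basis-pursuit) solver backs the same interface as
an independent cross-check on small systems. Negative reconstructed pixels
are kept for error computation and clipped only for display.

Two reset accountings are provided. The default uses the exactly recorded
reset flux, making the map tight (grating reconstruction errors ~0.015; the
residual is window sampling noise). The coarse-grained alternative
`m (θ̄ - V_Re)` mirrors the classical derivation and additionally carries
the threshold-crossing overshoot (the amount by which the voltage exceeds
threshold at a crossing, of order the impulse size); at these impulse sizes
that approximation alone raises grating errors to ~0.22. Reconstruction for
each window uses only that window's statistics; windows shorter than ten
metric bins are refused as statistically unreliable. Relative error is the
Euclidean quotient `||p - p_recon|| / ||p||` against the normalized truth.

## Synthetic stimuli

Gratings are binary square waves (stripe period side/5 by default),
horizontal for pool 1 and vertical for pool 2. Natural-scene surrogates are
Gaussian random fields with isotropic power spectrum `f^-2` (1/f amplitude),
affinely rescaled to [0, 1]: they match the frequency-domain sparsity that
drives compressive-sensing recovery (~75% of non-DC DCT energy in the lowest
tenth of frequencies) but contain none of the edges, occlusions or
higher-order structure of photographs, so reconstruction quality on real
scenes is not certified by these tests. All stimuli are normalized to mean
pixel value `m0` before use, making the feedforward drive of the two eyes
comparable.

## Problem sizes

Unit tests run 120-neuron pools for hundreds of ms; the integration layer is
exercised at full scale. The statistical suite uses the production
configuration (2 x 2000 neurons, `dt = 0.1 ms`): one 40 s rivalry run for
alternation and reconstruction checks, two 40 s ablation runs, ten 40 s
realizations for pooled duration statistics, and five-point
stimulus-strength sweeps at 20 s per point. The acceptance script uses ten
40 s realizations and a nineteen-point symmetric sweep at 25 s per point.

## Known limitations

* At the default parameters the rivalry regime is marginal: a minority of
  network realizations (and most runs with clearly unequal or weak stimuli,
  `m0 ≲ 0.45`) lock into winner-take-all for the whole 40 s. Pooled
  duration samples therefore mix alternating realizations with occasional
  full-length dominance stretches, giving a strongly right-skewed,
  nearly-exponential duration distribution (gamma shape ~1) rather than the
  narrow gamma (shape ~10, coefficient of variation ~0.3) reported for
  human observers. A narrow gamma with mean ~1.7 s would require a slow
  adaptation variable with a time constant comparable to the dominance
  duration itself; with the 160 ms threshold decay used here all adaptation
  state saturates within ~0.8 s, after which switching is hazard-flat.
* The low-strength reversal of the alternation-rate trend (rate rising
  again as common drive falls below ~0.25) does not occur: weak-drive runs
  freeze instead. The release mechanism is present only as a lengthening of
  dominance at weak drive.
* The initial transient reconstructs nearly as accurately as later windows
  under the default (measured-flux) accounting — its error exceeds the
  post-transient mean only marginally. The classical pronounced
  transient-degradation effect belongs to approximate accounting and to
  mixed-percept transients, neither of which the default pipeline produces.
* Euler stepping with start-of-step delivery slightly synchronizes spike
  arrival; halving `dt` changes single-pool rates by ~1.5% and duration
  statistics within their realization-to-realization spread.
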