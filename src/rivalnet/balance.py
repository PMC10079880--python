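"""Coarse-grained balanced-network theory for a single (dominant) pool.

In the large-network limit the net drive into a neuron of population ``k``,
``sqrt(K)/g_L * (f_k m0 + R_kE m_E + R_kI m_I)``, must stay finite as K grows,
which pins the population-averaged rates to the linear solution

    m_E = (|R_II| f_E - |R_EI| f_I) / (R_IE |R_EI| - R_EE |R_II|) * m0
    m_I = (R_IE  f_E - R_EE  f_I) / (R_IE |R_EI| - R_EE |R_II|) * m0

and requires the ordering f_E/f_I > |R_EI|/|R_II| > R_EE/R_IE for both rates
to be positive.  These rates are normalized units: the simulated gain curve
is tested for linearity in m0 and for E/I rate equality rather than for an
absolute match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import NetworkRealization, build_network
from .params import ModelParams
from .simulator import SimOutput, simulate, window_statistics
from .stimuli import StimulusImage, make_grating, normalize_stimulus

__all__ = ["BalanceReport", "balance_conditions", "theoretical_rates",
           "expected_offset", "predict_mean_voltages", "gain_curve"]


@dataclass
class BalanceReport:
    lhs_chain: Tuple[float, float, float]  # (f_E/f_I, |R_EI|/|R_II|, R_EE/R_IE)
    satisfied: bool
    m_E_theory: float
    m_I_theory: float


def balance_conditions(params: ModelParams) -> BalanceReport:
    """Evaluate the strict ordering f_E/f_I > |R_EI|/|R_II| > R_EE/R_IE."""
    if params.R_IE == 0 or params.R_II == 0 or params.f_I == 0:
        raise ZeroDivisionError("R_IE, R_II and f_I must be nonzero")
    chain = (params.f_E / params.f_I,
             abs(params.R_EI) / abs(params.R_II),
             params.R_EE / params.R_IE)
    ok = chain[0] > chain[1] > chain[2]
    if ok:
        mE, mI = theoretical_rates(params)
    else:
        mE = mI = float("nan")
    return BalanceReport(lhs_chain=chain, satisfied=ok,
                         m_E_theory=mE, m_I_theory=mI)


def theoretical_rates(params: ModelParams, m0: Optional[float] = None
                      ) -> Tuple[float, float]:
    """Balanced-limit population rates (normalized units), linear in m0."""
    if m0 is None:
        m0 = params.m0
    den = params.R_IE * abs(params.R_EI) - params.R_EE * abs(params.R_II)
    if den == 0:
        raise ZeroDivisionError(
            "degenerate parameters: R_IE|R_EI| - R_EE|R_II| = 0")
    mE = (abs(params.R_II) * params.f_E - abs(params.R_EI) * params.f_I) * m0 / den
    mI = (params.R_IE * params.f_E - params.R_EE * params.f_I) * m0 / den
    return mE, mI


def expected_offset(params: ModelParams, m_E: float, m_I: float
                    ) -> Tuple[float, float]:
    """Expected voltage offset ``sqrt(K)/g_L (f_k m0 + R_kE m_E + R_kI m_I)``.

    At the balanced-limit rates the bracket cancels exactly and both offsets
    vanish.
    """
    s = np.sqrt(params.K) / params.g_L
    dE = s * (params.f_E * params.m0 + params.R_EE * m_E + params.R_EI * m_I)
    dI = s * (params.f_I * params.m0 + params.R_IE * m_E + params.R_II * m_I)
    return float(dE), float(dI)


def predict_mean_voltages(
    network: NetworkRealization,
    stimulus: StimulusImage,
    m_own: np.ndarray,
    m_other: np.ndarray,
    theta_bar: np.ndarray,
    params: ModelParams,
    pool: int = 1,
) -> np.ndarray:
    """Forward input-output map: predicted mean voltage per neuron.

    ``v_bar = V_Re + (F p + R m_own + C_other m_other
    - m_own * (theta_bar - V_Re)) / g_L`` for the given pool, with rates in
    spikes/ms.
    """
    m_own = np.asarray(m_own, dtype=float)
    m_other = np.asarray(m_other, dtype=float)
    theta_bar = np.asarray(theta_bar, dtype=float)
    M = params.M
    if not (m_own.shape == m_other.shape == theta_bar.shape == (M,)):
        raise ValueError("per-neuron vectors must all have length M")
    if stimulus.n != network.n:
        raise ValueError("stimulus size does not match feedforward matrix")
    F = network.F1 if pool == 1 else network.F2
    R = network.R1 if pool == 1 else network.R2
    C_other = network.C2 if pool == 1 else network.C1
    # C matrices span the combined index space convention: rows are the
    # receiving pool, columns the sending pool
    drive = (np.asarray(F @ stimulus.vector).ravel()
             + np.asarray(R @ m_own).ravel()
             + np.asarray(C_other @ m_other).ravel()
             - m_own * (theta_bar - params.V_Re))
    return params.V_Re + drive / params.g_L


def gain_curve(
    params: ModelParams,
    m0_grid: Sequence[float],
    duration: float = 3000.0,
    seed: Optional[int] = None,
    warmup: float = 500.0,
    stimulus: Optional[StimulusImage] = None,
) -> pd.DataFrame:
    """Simulated population-averaged rates of an isolated pool versus m0.

    Cross-pool coupling and adaptation are switched off so each run probes
    the balanced gain of a single pool; rates are averaged after a warm-up.
    Returns a DataFrame with columns m0, rate_E, rate_I (spikes/ms).
    """
    base = params.replace(C_IE=0.0, adaptation_mode="none")
    m0_grid = [float(x) for x in m0_grid]
    rows = []
    ss = np.random.SeedSequence(seed)
    for m0, child in zip(m0_grid, ss.spawn(len(m0_grid))):
        p = base.replace(m0=m0, m0_2=m0)
        net_seed, sim_seed = (int(s % (2**31)) for s in child.generate_state(2))
        net = build_network(p, seed=net_seed)
        if stimulus is None:
            img = make_grating(p.side, "vertical")
        else:
            img = stimulus
        img = normalize_stimulus(img, m0)
        sim = simulate(net, (img, img), p, duration, seed=sim_seed)
        rate = window_statistics(sim, warmup, duration).rate
        rE = rate[sim.pool_slice(1, "E")].mean()
        rI = rate[sim.pool_slice(1, "I")].mean()
        rows.append({"m0": float(m0), "rate_E": float(rE),
                     "rate_I": float(rI)})
    return pd.DataFrame(rows)
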