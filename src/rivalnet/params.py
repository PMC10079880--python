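"""Model parameters for the two-pool balanced rivalry network.

All voltages are non-dimensionalized (reset potential ``V_Re = 0``, excitatory
firing threshold ``theta_E = 1``); rates carry units of spikes/ms and the leak
rate ``g_L`` is in 1/ms (the default 0.05/ms corresponds to the standard 20 ms
membrane time constant).  Synaptic weights follow the balanced-network scaling
``J = R_kl / sqrt(K)`` so that the mean feedforward drive into a neuron of
population ``k`` is ``sqrt(K) * f_k * m0``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import yaml

ADAPTATION_MODES = ("both", "excitatory_only", "none")


@dataclass
class ModelParams:
    """All scalar parameters of the network and its dynamics.

    Defaults reproduce the standard rivalry configuration: two pools of
    1000 excitatory + 1000 inhibitory neurons, mean in-degree 40 per
    population, balanced couplings (R_EE = R_IE = 1, R_EI = -2, R_II = -1.8),
    feedforward scalings f_E = 1 > f_I = 0.8, stimulus strength m0 = 0.5 and
    slow threshold adaptation (lambda = 0.00625/ms, phi = 0.005).
    """

    # recurrent couplings (dimensionless; excitatory > 0, inhibitory < 0)
    R_EE: float = 1.0
    R_IE: float = 1.0
    R_EI: float = -2.0
    R_II: float = -1.8
    # cross-pool excitatory -> inhibitory coupling
    C_IE: float = 1.0
    # population sizes and mean in-degree
    N_E: int = 1000
    N_I: int = 1000
    K: int = 40
    # feedforward scaling per population
    f_E: float = 1.0
    f_I: float = 0.8
    # stimulus strength (pool 1; pool 2 defaults to the same value)
    m0: float = 0.5
    m0_2: Optional[float] = None
    # thresholds / reset
    theta_E: float = 1.0
    theta_I: float = 0.8
    V_Re: float = 0.0
    # lower voltage bound: the inhibitory reversal potential in the standard
    # normalization (rest 0, threshold 1 map -70 mV, -55 mV; -80 mV -> -2/3).
    # Inhibitory impulses cannot drive the voltage below this value.
    V_floor: float = -2.0 / 3.0
    # leak and adaptation rates (1/ms) and threshold jump per spike
    g_L: float = 0.05
    lambda_adapt: float = 0.00625
    phi: float = 0.005
    # inhibition scaling factor (multiplies R_EI and R_II in both pools)
    S_I: float = 1.0
    adaptation_mode: str = "both"
    # stimulus size (defaults to 10 * N_E pixels) and integration step (ms)
    n_pixels: Optional[int] = None
    dt: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_pixels is None:
            self.n_pixels = 10 * self.N_E
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def M(self) -> int:
        """Neurons per pool."""
        return self.N_E + self.N_I

    @property
    def n(self) -> int:
        return int(self.n_pixels)

    @property
    def side(self) -> int:
        s = int(round(math.sqrt(self.n)))
        if s * s != self.n:
            raise ValueError(f"n_pixels={self.n} is not a perfect square")
        return s

    def m0_for_pool(self, pool: int) -> float:
        if pool == 1:
            return self.m0
        if pool == 2:
            return self.m0 if self.m0_2 is None else self.m0_2
        raise ValueError("pool must be 1 or 2")

    def validate(self) -> None:
        if not (self.R_EE > 0 and self.R_IE > 0 and self.C_IE >= 0):
            raise ValueError("excitatory couplings R_EE, R_IE must be > 0 "
                             "and C_IE >= 0")
        if not (self.R_EI < 0 and self.R_II < 0):
            raise ValueError("inhibitory couplings R_EI, R_II must be < 0")
        if not (1 <= self.K <= min(self.N_E, self.N_I)):
            raise ValueError(
                f"K={self.K} must satisfy 1 <= K <= min(N_E, N_I)")
        if not (self.theta_E > self.V_Re and self.theta_I > self.V_Re):
            raise ValueError("firing thresholds must exceed V_Re")
        if self.V_floor > self.V_Re:
            raise ValueError("V_floor must not exceed V_Re")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.f_E > self.f_I > 0):
            raise ValueError("balance requires f_E > f_I > 0")
        if self.g_L <= 0 or self.lambda_adapt < 0 or self.phi < 0:
            raise ValueError("g_L must be > 0; lambda_adapt, phi must be >= 0")
        if self.S_I < 0:
            raise ValueError("S_I must be >= 0")
        if self.adaptation_mode not in ADAPTATION_MODES:
            raise ValueError(
                f"adaptation_mode must be one of {ADAPTATION_MODES}")
        if self.n_pixels is not None and self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_file(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class RFParams:
    """Gaussian receptive-field sampling parameters.

    ``rho`` is the sampling probability when a pixel coincides with the
    receptive-field center and ``sigma`` the field width in pixel units.
    The defaults produce moderately sized fields on a 100x100 grid.
    """

    rho: float = 0.92
    sigma: float = 2.2

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("rho must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
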