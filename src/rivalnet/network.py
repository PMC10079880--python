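"""Random sparse connectivity realizations.

A pool holds ``M = N_E + N_I`` neurons ordered excitatory first.  Six sparse
matrices define a realization: intra-pool recurrent matrices ``R1``/``R2``
(M x M), cross-pool matrices ``C1``/``C2`` (nonzero only in the
inhibitory-row x excitatory-column block; ``C1`` carries connections whose
presynaptic neurons live in pool 1) and feedforward matrices ``F1``/``F2``
(M x n) mapping stimulus pixels to neurons.

All entries are independent Bernoulli draws.  A recurrent entry with
presynaptic population ``l`` is nonzero with probability ``K / N_l`` and has
magnitude ``R_kl / sqrt(K)`` (inhibitory entries additionally scaled by
``S_I``); self-connections are excluded.  Uniform feedforward entries are
nonzero with probability ``K / n`` and magnitude ``f_k / sqrt(K)``, giving an
expected drive of ``sqrt(K) f_k m0`` for a stimulus of mean ``m0``.
Receptive-field feedforward connectivity replaces the flat probability with a
Gaussian profile around a random center pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .params import ModelParams, RFParams

__all__ = [
    "NetworkRealization",
    "build_recurrent",
    "build_cross_pool",
    "build_feedforward_uniform",
    "rf_sampling_probability",
    "build_feedforward_rf",
    "build_network",
    "save_network",
    "load_network",
]


@dataclass
class NetworkRealization:
    """The six sampled connectivity matrices plus the seed that produced them."""

    R1: sp.csc_matrix
    R2: sp.csc_matrix
    C1: sp.csc_matrix
    C2: sp.csc_matrix
    F1: sp.csc_matrix
    F2: sp.csc_matrix
    seed: Optional[int] = None

    @property
    def M(self) -> int:
        return self.R1.shape[0]

    @property
    def n(self) -> int:
        return self.F1.shape[1]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def build_recurrent(params: ModelParams, rng) -> sp.csc_matrix:
    """Sample one intra-pool recurrent matrix.

    Entry (i, j) with presynaptic population ``l`` is nonzero with probability
    ``K / N_l``; nonzero magnitude ``R_kl / sqrt(K)``, inhibitory entries
    multiplied by ``S_I``.  The diagonal is forced to zero.
    """
    rng = _as_rng(rng)
    N_E, N_I, K = params.N_E, params.N_I, params.K
    M = N_E + N_I
    sq = math.sqrt(K)
    J = np.zeros((M, M))
    u = rng.random((M, M))
    # block weights indexed (post, pre)
    wEE = params.R_EE / sq
    wIE = params.R_IE / sq
    wEI = params.S_I * params.R_EI / sq
    wII = params.S_I * params.R_II / sq
    pE, pI = K / N_E, K / N_I
    J[:N_E, :N_E] = np.where(u[:N_E, :N_E] < pE, wEE, 0.0)
    J[N_E:, :N_E] = np.where(u[N_E:, :N_E] < pE, wIE, 0.0)
    J[:N_E, N_E:] = np.where(u[:N_E, N_E:] < pI, wEI, 0.0)
    J[N_E:, N_E:] = np.where(u[N_E:, N_E:] < pI, wII, 0.0)
    np.fill_diagonal(J, 0.0)
    return sp.csc_matrix(J)


def build_cross_pool(params: ModelParams, rng) -> sp.csc_matrix:
    """Sample one cross-pool matrix (excitatory -> inhibitory block only).

    Only entries with inhibitory postsynaptic rows and excitatory presynaptic
    columns may be nonzero, each with probability ``K / N_E`` and positive
    magnitude ``C_IE / sqrt(K)``.
    """
    rng = _as_rng(rng)
    N_E, N_I, K = params.N_E, params.N_I, params.K
    M = N_E + N_I
    w = params.C_IE / math.sqrt(K)
    block = np.where(rng.random((N_I, N_E)) < K / N_E, w, 0.0)
    C = sp.lil_matrix((M, M))
    C[N_E:, :N_E] = block
    return C.tocsc()


def build_feedforward_uniform(params: ModelParams, rng) -> sp.csc_matrix:
    """Sample a uniform feedforward matrix (M x n).

    Each entry is nonzero with probability ``K / n`` and magnitude
    ``f_k / sqrt(K)`` for a row in population ``k``.
    """
    rng = _as_rng(rng)
    N_E, K, n = params.N_E, params.K, params.n
    M = params.M
    p = min(K / n, 1.0)
    sq = math.sqrt(K)
    rows, cols, vals = [], [], []
    chunk = max(1, int(4e6 // n))
    for start in range(0, M, chunk):
        stop = min(start + chunk, M)
        u = rng.random((stop - start, n))
        r, c = np.nonzero(u < p)
        rows.append(r + start)
        cols.append(c)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.where(rows < N_E, params.f_E / sq, params.f_I / sq)
    return sp.coo_matrix((vals, (rows, cols)), shape=(M, n)).tocsc()


def rf_sampling_probability(center, pixel, rf: RFParams):
    """Gaussian receptive-field sampling probability.

    ``rho * exp(-[(x_i - x_j)^2 + (y_i - y_j)^2] / (2 sigma^2))`` for a
    receptive field centered at ``center`` and a pixel at ``pixel`` (both
    (row, col) coordinate pairs; arrays broadcast).
    """
    cx, cy = np.asarray(center[0]), np.asarray(center[1])
    px, py = np.asarray(pixel[0]), np.asarray(pixel[1])
    d2 = (cx - px) ** 2 + (cy - py) ** 2
    return rf.rho * np.exp(-d2 / (2.0 * rf.sigma**2))


def build_feedforward_rf(params: ModelParams, rf: RFParams, rng) -> sp.csc_matrix:
    """Sample a receptive-field-structured feedforward matrix.

    Each row is assigned a distinct uniformly random center on the
    ``side x side`` pixel grid; entry (i, j) is an independent Bernoulli draw
    with success probability from :func:`rf_sampling_probability` and nonzero
    magnitude ``f_k / sqrt(K)``.
    """
    rng = _as_rng(rng)
    side = params.side
    M, N_E = params.M, params.N_E
    if M > side * side:
        raise ValueError(
            f"cannot place {M} distinct receptive-field centers on a "
            f"{side}x{side} grid")
    centers = rng.choice(side * side, size=M, replace=False)
    cx, cy = np.divmod(centers, side)  # (row, col) on the grid
    sq = math.sqrt(params.K)
    half = int(math.ceil(5.0 * rf.sigma))
    coords = np.arange(side)
    rows_out, cols_out = [], []
    for i in range(M):
        x0, y0 = int(cx[i]), int(cy[i])
        xs = coords[max(0, x0 - half):min(side, x0 + half + 1)]
        ys = coords[max(0, y0 - half):min(side, y0 + half + 1)]
        gx = np.exp(-((xs - x0) ** 2) / (2 * rf.sigma**2))
        gy = np.exp(-((ys - y0) ** 2) / (2 * rf.sigma**2))
        p = rf.rho * np.outer(gx, gy)
        hit = rng.random(p.shape) < p
        hx, hy = np.nonzero(hit)
        cols = (xs[hx]) * side + ys[hy]  # row-major vectorization
        rows_out.append(np.full(cols.size, i))
        cols_out.append(cols)
    rows = np.concatenate(rows_out)
    cols = np.concatenate(cols_out)
    vals = np.where(rows < N_E, params.f_E / sq, params.f_I / sq)
    return sp.coo_matrix((vals, (rows, cols)), shape=(M, params.n)).tocsc()


def build_network(
    params: ModelParams,
    seed: Optional[int] = None,
    rf: Optional[RFParams] = None,
) -> NetworkRealization:
    """Build all six connectivity matrices from a single seed.

    When ``rf`` is given, both feedforward matrices use receptive-field
    structure; otherwise they are uniform Bernoulli.
    """
    if seed is None:
        seed = params.seed
    rng = _as_rng(seed)
    R1 = build_recurrent(params, rng)
    R2 = build_recurrent(params, rng)
    C1 = build_cross_pool(params, rng)
    C2 = build_cross_pool(params, rng)
    if rf is None:
        F1 = build_feedforward_uniform(params, rng)
        F2 = build_feedforward_uniform(params, rng)
    else:
        F1 = build_feedforward_rf(params, rf, rng)
        F2 = build_feedforward_rf(params, rf, rng)
    return NetworkRealization(R1=R1, R2=R2, C1=C1, C2=C2, F1=F1, F2=F2,
                              seed=seed)


def save_network(net: NetworkRealization, path, params: Optional[ModelParams] = None) -> None:
    """Serialize a realization to a compressed npz archive (triplet format)."""
    arrays = {}
    for name in ("R1", "R2", "C1", "C2", "F1", "F2"):
        m = getattr(net, name).tocoo()
        arrays[f"{name}_row"] = m.row
        arrays[f"{name}_col"] = m.col
        arrays[f"{name}_val"] = m.data
        arrays[f"{name}_shape"] = np.array(m.shape)
    arrays["seed"] = np.array(-1 if net.seed is None else net.seed)
    if params is not None:
        import json

        arrays["params_json"] = np.frombuffer(
            json.dumps(params.to_dict()).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_network(path) -> NetworkRealization:
    with np.load(path) as z:
        mats = {}
        for name in ("R1", "R2", "C1", "C2", "F1", "F2"):
            shape = tuple(z[f"{name}_shape"])
            mats[name] = sp.coo_matrix(
                (z[f"{name}_val"], (z[f"{name}_row"], z[f"{name}_col"])),
                shape=shape).tocsc()
        seed = int(z["seed"])
    return NetworkRealization(seed=None if seed < 0 else seed, **mats)
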