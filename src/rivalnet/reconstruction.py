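"""Percept reconstruction by compressive sensing.

During a dominance period the input-output map

    v_bar = V_Re + (F p + R m_own + C_other m_other
                    - m_own * (theta_bar - V_Re)) / g_L

is rearranged into the underdetermined linear system ``F p = b`` for the
unknown dominant stimulus ``p``.  Since the stimuli are sparse in a frequency
basis, the system is solved greedily by orthogonal matching pursuit over the
composite operator (feedforward matrix o inverse 2-D DCT); an
equality-constrained l1 solver is kept behind the same interface as an
independent cross-check on small problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.fft import dctn, idctn
from scipy.linalg import cho_solve, solve_triangular

from .dominance import DominanceSegment
from .network import NetworkRealization
from .params import ModelParams
from .simulator import SimOutput, window_statistics
from .stimuli import StimulusImage

__all__ = [
    "LinearSystem", "ReconstructionResult", "assemble_system", "omp_solve",
    "l1_solve", "relative_error", "reconstruct_run", "dct2", "idct2",
]


def dct2(img: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II."""
    return dctn(img, norm="ortho")


def idct2(coef: np.ndarray) -> np.ndarray:
    return idctn(coef, norm="ortho")


@dataclass
class LinearSystem:
    measurement_matrix: sp.spmatrix   # dominant pool's feedforward matrix
    observation: np.ndarray           # b, length M
    side: int
    segment_id: Optional[int] = None
    is_transient: bool = False
    pool: Optional[int] = None


@dataclass
class ReconstructionResult:
    percept: np.ndarray               # (side, side); may contain negatives
    coefficients: np.ndarray          # dense DCT coefficient vector
    atoms_used: int
    segment_id: Optional[int] = None
    is_transient: bool = False
    pool: Optional[int] = None
    relative_error: Optional[float] = None

    def clipped_image(self) -> StimulusImage:
        """Display form with negative pixels clipped to zero."""
        return StimulusImage(np.clip(self.percept, 0.0, None))


def assemble_system(
    network: NetworkRealization,
    stats,
    dominant_pool: int,
    params: ModelParams,
    segment_id: Optional[int] = None,
    is_transient: bool = False,
    reset_accounting: str = "measured",
) -> LinearSystem:
    """Build ``F p = b`` from one dominance window's statistics.

    ``stats`` is a :class:`~rivalnet.simulator.WindowStats` (or a
    (rate, vmean, thmean) triple) over all ``2M`` neurons; rates in
    spikes/ms.  The observation uses the dominant pool's statistics and the
    suppressed pool's rates through the cross-pool matrix:
    ``b = g_L (v_bar - V_Re) - R m_own - C_other m_other
    + (reset flux) - clamp_rate``,
    where ``clamp_rate`` is the recorded mean voltage flux injected by the
    lower voltage bound (zero when voltages never reach ``V_floor``).

    ``reset_accounting`` selects how the voltage removed by spike resets is
    represented: ``"measured"`` uses the exactly recorded per-neuron reset
    flux; ``"threshold"`` uses the coarse-grained approximation
    ``m_own * (theta_bar - V_Re)``, which additionally carries the
    threshold-crossing overshoot as approximation error.
    """
    clamp = None
    reset = None
    if hasattr(stats, "clamp_rate"):
        clamp = np.asarray(stats.clamp_rate, dtype=float)
        reset = np.asarray(stats.reset_rate, dtype=float)
    if reset_accounting not in ("measured", "threshold"):
        raise ValueError("reset_accounting must be 'measured' or 'threshold'")
    if reset_accounting == "measured" and reset is None:
        raise ValueError(
            "measured reset accounting needs WindowStats with flux fields")
    rate, vmean, thmean = (np.asarray(a, dtype=float) for a in stats)
    M = params.M
    if rate.shape[0] != 2 * M:
        raise ValueError("statistics must cover both pools (length 2M)")
    if dominant_pool == 1:
        own, other = slice(0, M), slice(M, 2 * M)
        F, R, C_other = network.F1, network.R1, network.C2
    elif dominant_pool == 2:
        own, other = slice(M, 2 * M), slice(0, M)
        F, R, C_other = network.F2, network.R2, network.C1
    else:
        raise ValueError("dominant_pool must be 1 or 2")
    m_own, m_oth = rate[own], rate[other]
    b = (params.g_L * (vmean[own] - params.V_Re)
         - np.asarray(R @ m_own).ravel()
         - np.asarray(C_other @ m_oth).ravel())
    if reset_accounting == "measured":
        b = b + reset[own]
    else:
        b = b + m_own * (thmean[own] - params.V_Re)
    if clamp is not None:
        b = b - clamp[own]
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite observation vector")
    return LinearSystem(measurement_matrix=F.tocsr(), observation=b,
                        side=params.side, segment_id=segment_id,
                        is_transient=is_transient, pool=dominant_pool)


def _omp_greedy(apply_AT, get_col, b, n_atoms, budget, tol):
    """Greedy OMP over an implicit dictionary.

    ``apply_AT(r)`` returns atom correlations with the residual;
    ``get_col(j)`` materializes one dictionary column.  Returns
    (selected atom indices, coefficients, residual).
    """
    m = b.shape[0]
    norm_b = float(np.linalg.norm(b))
    if norm_b == 0 or budget == 0:
        return [], np.zeros(0), b.copy()
    Phi = np.empty((m, budget))
    L = np.zeros((budget, budget))
    atb = np.empty(budget)
    sel: List[int] = []
    r = b.copy()
    x = np.zeros(0)
    for it in range(budget):
        c = apply_AT(r)
        c[sel] = 0.0
        j = int(np.argmax(np.abs(c)))
        if abs(c[j]) < 1e-13 * norm_b:
            break
        a = get_col(j)
        aa = float(a @ a)
        if aa <= 0:
            break
        s = len(sel)
        if s == 0:
            L[0, 0] = math.sqrt(aa)
        else:
            w = solve_triangular(L[:s, :s], Phi[:, :s].T @ a, lower=True)
            d2 = aa - float(w @ w)
            if d2 <= 1e-12 * aa:
                break  # numerically dependent atom; stop
            L[s, :s] = w
            L[s, s] = math.sqrt(d2)
        Phi[:, s] = a
        atb[s] = float(a @ b)
        sel.append(j)
        s += 1
        x = cho_solve((L[:s, :s], True), atb[:s])
        r = b - Phi[:, :s] @ x
        if np.linalg.norm(r) / norm_b < tol:
            break
    return sel, x, r


def omp_solve(
    system: LinearSystem,
    sparsity_budget: Optional[int] = None,
    residual_tol: float = 1e-6,
) -> ReconstructionResult:
    """Recover the percept from a linear system via OMP in the 2-D DCT basis.

    Atom selection runs on the composite operator ``F o idct2``; the solver
    stops at the sparsity budget (default rows/4) or when the relative
    residual drops below ``residual_tol``.  A zero observation yields a zero
    image (flagged by ``atoms_used == 0``), not an exception.
    """
    F = system.measurement_matrix
    b = system.observation
    side = system.side
    n = side * side
    m = F.shape[0]
    if sparsity_budget is None:
        sparsity_budget = m // 4
    if sparsity_budget >= m:
        raise ValueError("sparsity budget must be below the number of rows")
    FT = F.T.tocsr()

    def apply_AT(r):
        return dct2(np.asarray(FT @ r).reshape(side, side)).ravel()

    def get_col(j):
        e = np.zeros((side, side))
        e[divmod(j, side)] = 1.0
        return np.asarray(F @ idct2(e).ravel()).ravel()

    sel, x, _ = _omp_greedy(apply_AT, get_col, b, n, sparsity_budget,
                            residual_tol)
    coef = np.zeros(n)
    coef[sel] = x
    percept = idct2(coef.reshape(side, side))
    return ReconstructionResult(
        percept=percept, coefficients=coef, atoms_used=len(sel),
        segment_id=system.segment_id, is_transient=system.is_transient,
        pool=system.pool)


def l1_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Equality-constrained minimum-l1 solution (basis pursuit).

    Dense linear program via scipy; intended as an independent cross-check on
    small systems, not for production-size reconstructions.
    """
    from scipy.optimize import linprog

    A = np.asarray(A, dtype=float)
    m, n = A.shape
    res = linprog(
        c=np.ones(2 * n),
        A_eq=np.hstack([A, -A]),
        b_eq=np.asarray(b, dtype=float),
        bounds=[(0, None)] * (2 * n),
        method="highs")
    if not res.success:
        raise RuntimeError(f"l1 solve failed: {res.message}")
    return res.x[:n] - res.x[n:]


def relative_error(truth, recon) -> float:
    """Euclidean relative error ||p - p_recon|| / ||p||."""
    p = truth.vector if isinstance(truth, StimulusImage) else np.ravel(truth)
    q = recon.vector if isinstance(recon, StimulusImage) else np.ravel(recon)
    if p.shape != q.shape:
        raise ValueError("truth and reconstruction sizes differ")
    norm = np.linalg.norm(p)
    if norm == 0:
        raise ValueError("zero-norm ground truth")
    return float(np.linalg.norm(p - q) / norm)


def reconstruct_run(
    sim: SimOutput,
    network: NetworkRealization,
    segments: Sequence[DominanceSegment],
    params: ModelParams,
    truths: Optional[Sequence[StimulusImage]] = None,
    sparsity_budget: Optional[int] = None,
    residual_tol: float = 1e-6,
    min_bins: int = 10,
    max_data_ms: Optional[float] = None,
    reset_accounting: str = "measured",
) -> List[ReconstructionResult]:
    """One percept reconstruction per dominance window.

    Each reconstruction uses only the window statistics from within its own
    segment (the transient window is reconstructed too, flagged).
    Non-transient segments shorter than ``min_bins`` metric bins are skipped
    as statistically unreliable.  ``max_data_ms`` truncates each window to
    its initial portion (rapid-encoding experiments).
    """
    results: List[ReconstructionResult] = []
    for idx, seg in enumerate(segments):
        n_seg_bins = int(round(seg.duration / sim.bin_ms))
        if not seg.is_transient and n_seg_bins < min_bins:
            continue
        t_end = seg.t_end
        if max_data_ms is not None:
            t_end = min(t_end, seg.t_start + max_data_ms)
        try:
            stats = window_statistics(sim, seg.t_start, t_end)
        except ValueError:
            continue
        system = assemble_system(network, stats, seg.pool, params,
                                 segment_id=idx, is_transient=seg.is_transient,
                                 reset_accounting=reset_accounting)
        result = omp_solve(system, sparsity_budget=sparsity_budget,
                           residual_tol=residual_tol)
        if truths is not None:
            truth = truths[seg.pool - 1]
            result.relative_error = relative_error(truth, result.percept)
        results.append(result)
    return results
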