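"""Non-negative factorization engines.

Implements the multiplicative-update rules used throughout the pipeline:

* full NMF, ``M ~ W H`` with both factors free (Lee & Seung updates), for
  synergy extraction;
* fixed-component reconstruction (NNR), where one factor is frozen to a
  healthy template and only the other is updated:

  - fixed W:  ``H <- H * (W^T M) / (W^T W H)``
  - fixed H:  ``W <- W * (M H^T) / (W H H^T)``

Each update multiplies the current factor elementwise by a nonnegative ratio,
so nonnegativity is preserved and the squared reconstruction error is
non-increasing at every iteration. A small epsilon guards the denominator
against 0/0 without perturbing results at float64 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError

EPS = 1e-12

__all__ = ["FactorizationResult", "multiplicative_nmf", "nmf", "nnr_fixed_w", "nnr_fixed_h", "compute_vaf"]


@dataclass
class FactorizationResult:
    """Outcome of one multiplicative-update run."""

    W: np.ndarray
    H: np.ndarray
    error_history: np.ndarray  # squared Frobenius error per iteration
    n_iter: int
    converged: bool

    @property
    def final_error(self) -> float:
        return float(self.error_history[-1])


def _check_nonneg(M: np.ndarray, name: str = "M") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise InvalidParameterError(f"{name} must be a 2-D matrix, got ndim={M.ndim}")
    if np.any(M < 0):
        raise DegenerateInputError(f"{name} has negative entries; factorization requires nonnegative input")
    return M


def _sq_error(M: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = M - W @ H
    return float(np.sum(R * R))


def multiplicative_nmf(
    M: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    update_w: bool = True,
    update_h: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> FactorizationResult:
    """Run multiplicative updates from the given initialization.

    ``tol`` is the relative decrease of the squared error between consecutive
    iterations below which the run stops. Frozen factors are returned
    bit-identical to their input.
    """
    M = _check_nonneg(M)
    W = np.asarray(W, dtype=float).copy()
    H = np.asarray(H, dtype=float).copy()
    errors = [_sq_error(M, W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if update_h:
            H *= (W.T @ M) / (W.T @ W @ H + EPS)
        if update_w:
            W *= (M @ H.T) / (W @ H @ H.T + EPS)
        err = _sq_error(M, W, H)
        errors.append(err)
        prev = errors[-2]
        if prev - err <= tol * max(prev, EPS):
            converged = True
            break
    return FactorizationResult(W, H, np.array(errors), it, converged)


def _random_init(rng: np.random.Generator, M: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    # scale so W H starts at roughly the magnitude of M
    scale = np.sqrt(max(M.mean(), EPS) / rank)
    W = rng.uniform(0.0, 1.0, size=(M.shape[0], rank)) * 2 * scale
    H = rng.uniform(0.0, 1.0, size=(rank, M.shape[1])) * 2 * scale
    return W, H


def nmf(
    M: np.ndarray,
    rank: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> FactorizationResult:
    """Best-of-restarts NMF with seeded uniform random initialization.

    Restarts mitigate the local minima of the multiplicative updates; the run
    with the lowest final squared error wins. Fixed seed gives bit-identical
    results.
    """
    M = _check_nonneg(M)
    if not np.any(M > 0):
        raise DegenerateInputError("all-zero matrix cannot be factorized")
    if not 1 <= rank <= min(M.shape):
        raise InvalidParameterError(f"rank {rank} outside [1, min{M.shape}]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best: FactorizationResult | None = None
    for _ in range(max(1, n_restarts)):
        W0, H0 = _random_init(rng, M, rank)
        res = multiplicative_nmf(M, W0, H0, max_iter=max_iter, tol=tol)
        if best is None or res.final_error < best.final_error:
            best = res
    assert best is not None
    return best


def nnr_fixed_w(
    M: np.ndarray,
    W_fixed: np.ndarray,
    seed: int | np.random.Generator = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> FactorizationResult:
    """Reconstruct M with frozen synergy weights: only H is updated."""
    M = _check_nonneg(M)
    W_fixed = _check_nonneg(np.asarray(W_fixed, dtype=float), "W_fixed")
    if W_fixed.shape[0] != M.shape[0]:
        raise InvalidParameterError(
            f"W_fixed has {W_fixed.shape[0]} rows but M has {M.shape[0]} muscles"
        )
    norms = np.linalg.norm(W_fixed, axis=0)
    if np.any(norms <= EPS):
        raise DegenerateInputError("W_fixed contains a zero weight column")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _, H0 = _random_init(rng, M, W_fixed.shape[1])
    res = multiplicative_nmf(M, W_fixed, H0, update_w=False, max_iter=max_iter, tol=tol)
    res.W = W_fixed  # bit-identical frozen part
    return res


def nnr_fixed_h(
    M: np.ndarray,
    H_fixed: np.ndarray,
    seed: int | np.random.Generator = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> FactorizationResult:
    """Reconstruct M with frozen activation profiles: only W is updated."""
    M = _check_nonneg(M)
    H_fixed = _check_nonneg(np.asarray(H_fixed, dtype=float), "H_fixed")
    if H_fixed.shape[1] != M.shape[1]:
        raise InvalidParameterError(
            f"H_fixed has {H_fixed.shape[1]} columns but M has {M.shape[1]} samples"
        )
    if np.any(np.linalg.norm(H_fixed, axis=1) <= EPS):
        raise DegenerateInputError("H_fixed contains a zero activation row")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    W0, _ = _random_init(rng, M, H_fixed.shape[0])
    res = multiplicative_nmf(M, W0, H_fixed, update_h=False, max_iter=max_iter, tol=tol)
    res.H = H_fixed
    return res


def compute_vaf(M: np.ndarray, W: np.ndarray, H: np.ndarray) -> tuple[float, np.ndarray]:
    """Variability accounted for, total and per muscle (row).

    VAF = 1 - SSE/SST with uncentered SST (sum of squared entries of M).
    Rows with zero SST have undefined VAF and are reported as NaN rather
    than silently zero; an all-zero M yields NaN total VAF.
    """
    M = np.asarray(M, dtype=float)
    R = M - np.asarray(W) @ np.asarray(H)
    sse_rows = np.sum(R * R, axis=1)
    sst_rows = np.sum(M * M, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_muscle = np.where(sst_rows > 0, 1.0 - sse_rows / sst_rows, np.nan)
    sst = sst_rows.sum()
    total = 1.0 - sse_rows.sum() / sst if sst > 0 else float("nan")
    return float(total), per_muscle
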