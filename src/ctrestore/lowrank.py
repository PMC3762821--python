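"""Sparse + low-rank decomposition solvers for stacked image sequences.

Three models decompose the data matrix D (columns = vectorized frames):

* ``rpca_alm`` — robust PCA, ``min ||A||_* + lam*||E||_1  s.t.  D = A + E``,
  solved by the inexact augmented Lagrange multiplier (ALM) scheme with
  singular-value thresholding for A and elementwise shrinkage for E.
* ``ladmap_rpca`` — the same convex program solved by the linearized
  alternating direction method with adaptive penalty (LADMAP).  For the
  plain D = A + E constraint the linear maps are identities, so the
  linearization constant is 1 and the method differs from ALM in its
  Gauss-Seidel update order, its adaptive penalty growth rule, and its
  two-part stopping criterion.
* ``godec`` — approximate decomposition X = L + S + G under hard rank and
  cardinality constraints, alternating a bilateral-random-projection
  rank-r approximation for L with a keep-k-largest projection for S; the
  residual G absorbs dense noise.

All solvers accept/return plain dense float64 matrices.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.linalg

__all__ = [
    "SolverOptions",
    "DecompositionResult",
    "soft_threshold",
    "svd_shrink",
    "rpca_alm",
    "ladmap_rpca",
    "brp_approx",
    "godec",
]


@dataclass
class SolverOptions:
    """Tuning knobs shared by the three solvers.

    ``lam`` defaults to 1/sqrt(max(m, n)) (set at solve time when None),
    the standard robust-PCA weighting.  ``mu0``/``rho``/``mu_max`` control
    the augmented-Lagrangian penalty schedule; ``r``/``k``/``q``/``seed``
    only matter for GoDec (target rank, sparse cardinality, power
    iterations, RNG seed).
    """

    lam: float | None = None
    mu0: float | None = None          # default 1.25 / ||D||_2
    rho: float = 1.5
    mu_max: float | None = None       # default 1e7 * mu0
    tol: float = 1e-7
    max_iter: int = 500
    r: int = 1
    k: int = 0
    q: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.r < 1:
            raise ValueError("target rank r must be >= 1")
        if self.k < 0:
            raise ValueError("cardinality k must be >= 0")


@dataclass
class DecompositionResult:
    """Low-rank + sparse (+ noise) split of a data matrix with diagnostics."""

    low_rank: np.ndarray
    sparse: np.ndarray
    model: Literal["rpca", "ladmap", "godec"]
    iterations: int
    residual: float                  # relative Frobenius constraint residual
    converged: bool
    noise: np.ndarray | None = None  # GoDec only
    rank_used: int = 0
    card_used: int = 0
    objective_history: list[float] = field(default_factory=list)
    mu_history: list[float] = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        out = self.low_rank + self.sparse
        if self.noise is not None:
            out = out + self.noise
        return out

    def save(self, path: str | Path) -> None:
        """Serialize matrices + diagnostics to an .npz-in-zip archive."""
        path = Path(path)
        arrays = {"low_rank": self.low_rank, "sparse": self.sparse}
        if self.noise is not None:
            arrays["noise"] = self.noise
        meta = {
            "model": self.model,
            "iterations": self.iterations,
            "residual": self.residual,
            "converged": self.converged,
            "rank_used": self.rank_used,
            "card_used": self.card_used,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, arr in arrays.items():
                import io

                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"{name}.npy", buf.getvalue())
            zf.writestr("diagnostics.json", json.dumps(meta, indent=2))


def _effective_rank(A: np.ndarray, rel_tol: float = 1e-9) -> int:
    s = scipy.linalg.svdvals(A)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rel_tol * s[0]))


def soft_threshold(X: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage sign(x) * max(|x| - tau, 0).

    This is the proximal operator of ``tau*||.||_1``: it minimizes
    ``tau*||E||_1 + 0.5*||E - X||_F^2``.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    X = np.asarray(X, dtype=np.float64)
    return np.sign(X) * np.maximum(np.abs(X) - tau, 0.0)


def svd_shrink(X: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value thresholding: U * soft(S, tau) * Vt.

    Proximal operator of ``tau*||.||_*`` (nuclear norm); shrinks each
    singular value by tau and drops those below it.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    U, s, Vt = scipy.linalg.svd(np.asarray(X, dtype=np.float64),
                                full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(X, dtype=np.float64)
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _resolve_penalty(D: np.ndarray, opts: SolverOptions):
    m, n = D.shape
    lam = opts.lam if opts.lam is not None else 1.0 / np.sqrt(max(m, n))
    norm2 = scipy.linalg.svdvals(D)[0] if np.any(D) else 1.0
    mu = opts.mu0 if opts.mu0 is not None else 1.25 / norm2
    mu_max = opts.mu_max if opts.mu_max is not None else 1e7 * mu
    return lam, mu, mu_max, norm2


def rpca_alm(D: np.ndarray, opts: SolverOptions | None = None) -> DecompositionResult:
    """Robust PCA by the inexact augmented Lagrange multiplier method.

    Alternates::

        E <- soft_threshold(D - A + Y/mu, lam/mu)
        A <- svd_shrink(D - E + Y/mu, 1/mu)
        Y <- Y + mu*(D - A - E)
        mu <- min(rho*mu, mu_max)

    until ``||D - A - E||_F / ||D||_F <= tol`` or ``max_iter``.
    """
    opts = opts or SolverOptions()
    D = np.asarray(D, dtype=np.float64)
    if not np.all(np.isfinite(D)):
        raise ValueError("input matrix contains non-finite values")
    lam, mu, mu_max, norm2 = _resolve_penalty(D, opts)
    normD = np.linalg.norm(D)
    if normD == 0:
        z = np.zeros_like(D)
        return DecompositionResult(z, z.copy(), "rpca", 0, 0.0, True)

    # standard dual initialization: Y = D / max(||D||_2, ||D||_inf / lam)
    Y = D / max(norm2, np.abs(D).max() / lam)
    A = np.zeros_like(D)
    E = np.zeros_like(D)
    residual = np.inf
    converged = False
    mu_hist: list[float] = []
    it = 0
    for it in range(1, opts.max_iter + 1):
        E = soft_threshold(D - A + Y / mu, lam / mu)
        A = svd_shrink(D - E + Y / mu, 1.0 / mu)
        R = D - A - E
        Y = Y + mu * R
        mu_hist.append(mu)
        mu = min(opts.rho * mu, mu_max)
        residual = np.linalg.norm(R) / normD
        if residual <= opts.tol:
            converged = True
            break

    return DecompositionResult(
        low_rank=A, sparse=E, model="rpca", iterations=it,
        residual=float(residual), converged=converged,
        rank_used=_effective_rank(A), card_used=int(np.count_nonzero(E)),
        mu_history=mu_hist,
    )


def ladmap_rpca(D: np.ndarray, opts: SolverOptions | None = None,
                tol2: float = 1e-5, rho0: float | None = None,
                eps2: float = 1e-4) -> DecompositionResult:
    """LADMAP solver for the robust-PCA program, D = A + E specialization.

    With identity constraint maps the linearization constant is 1, so the
    proximal updates match ALM's but are applied Gauss-Seidel style with
    the *adaptive* penalty rule: mu grows by rho0 only when the iterates
    have nearly stabilized (``mu * max(dA, dE) / ||D|| < eps2``), else it
    is held.  Stops when both the constraint residual (< tol) and the
    relative iterate change (< tol2) are small.
    """
    opts = opts or SolverOptions()
    D = np.asarray(D, dtype=np.float64)
    if not np.all(np.isfinite(D)):
        raise ValueError("input matrix contains non-finite values")
    lam, mu, mu_max, norm2 = _resolve_penalty(D, opts)
    rho0 = rho0 if rho0 is not None else opts.rho
    normD = np.linalg.norm(D)
    if normD == 0:
        z = np.zeros_like(D)
        return DecompositionResult(z, z.copy(), "ladmap", 1, 0.0, True)

    Y = np.zeros_like(D)
    A = np.zeros_like(D)
    E = np.zeros_like(D)
    residual = np.inf
    converged = False
    mu_hist: list[float] = []
    it = 0
    for it in range(1, opts.max_iter + 1):
        A_new = svd_shrink(D - E - Y / mu, 1.0 / mu)
        E_new = soft_threshold(D - A_new - Y / mu, lam / mu)
        R = A_new + E_new - D
        Y = Y + mu * R
        dA = np.linalg.norm(A_new - A)
        dE = np.linalg.norm(E_new - E)
        A, E = A_new, E_new
        mu_hist.append(mu)
        residual = np.linalg.norm(R) / normD
        change = mu * max(dA, dE) / normD
        if residual <= opts.tol and change <= tol2:
            converged = True
            break
        # adaptive penalty: grow only once the iterates settle
        rho = rho0 if change < eps2 else 1.0
        mu = min(rho * mu, mu_max)

    return DecompositionResult(
        low_rank=A, sparse=E, model="ladmap", iterations=it,
        residual=float(residual), converged=converged,
        rank_used=_effective_rank(A), card_used=int(np.count_nonzero(E)),
        mu_history=mu_hist,
    )


def brp_approx(X: np.ndarray, r: int, q: int = 2,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Rank-<=r approximation via bilateral random projections.

    Projects X onto r random directions from both sides
    (Y1 = X A1, Y2 = X' Y1), refines with q power iterations
    (Y1 <- X Y2, Y2 <- X' Y1), re-orthogonalizes both bases by QR and
    returns ``Q1 (Q1' X Q2) Q2'``.  Deterministic under a fixed seed;
    exact (to rounding) when rank(X) <= r.
    """
    X = np.asarray(X, dtype=np.float64)
    m, n = X.shape
    if not 1 <= r <= min(m, n):
        raise ValueError(f"rank r={r} must lie in [1, {min(m, n)}]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    A1 = rng.standard_normal((n, r))
    Y1 = X @ A1
    Y2 = X.T @ Y1
    for _ in range(max(q, 0)):
        Y1 = X @ Y2
        Y2 = X.T @ Y1
    Q1, _ = scipy.linalg.qr(Y1, mode="economic")
    Q2, _ = scipy.linalg.qr(Y2, mode="economic")
    return Q1 @ (Q1.T @ X @ Q2) @ Q2.T


def _keep_k_largest(X: np.ndarray, k: int) -> np.ndarray:
    """Hard cardinality projection: zero all but the k largest |entries|.

    Ties at the k-th magnitude break by scan order (first kept), via a
    stable sort on (-|x|, flat index).
    """
    if k <= 0:
        return np.zeros_like(X)
    flat = X.reshape(-1)
    if k >= flat.size:
        return X.copy()
    order = np.argsort(-np.abs(flat), kind="stable")
    out = np.zeros_like(flat)
    idx = order[:k]
    out[idx] = flat[idx]
    return out.reshape(X.shape)


def godec(X: np.ndarray, opts: SolverOptions | None = None) -> DecompositionResult:
    """GoDec: X = L + S + G with rank(L) <= r and card(S) <= k.

    Alternates ``L <- rank-r approx of (X - S)`` (bilateral random
    projections; exact truncated SVD as a fallback whenever the randomized
    step would raise the residual, keeping the objective monotone) and
    ``S <- keep k largest entries of (X - L)``, until the relative change
    of ||X - L - S||_F^2 drops below tol.  G = X - L - S is returned as
    the noise component.
    """
    opts = opts or SolverOptions()
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    r, k = opts.r, opts.k
    if r > min(X.shape):
        raise ValueError(f"rank r={r} exceeds min(dims)={min(X.shape)}")
    rng = np.random.default_rng(opts.seed)
    normX2 = np.sum(X * X)
    if normX2 == 0:
        z = np.zeros_like(X)
        return DecompositionResult(z, z.copy(), "godec", 0, 0.0, True,
                                   noise=z.copy())

    L = np.zeros_like(X)
    S = np.zeros_like(X)
    obj_prev = normX2
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        T = X - S
        L_new = brp_approx(T, r, q=opts.q, seed=rng)
        if np.linalg.norm(T - L_new) > np.linalg.norm(T - L):
            U, s, Vt = scipy.linalg.svd(T, full_matrices=False)
            L_new = (U[:, :r] * s[:r]) @ Vt[:r]
        L = L_new
        S = _keep_k_largest(X - L, k)
        obj = float(np.sum((X - L - S) ** 2))
        history.append(obj)
        if abs(obj_prev - obj) <= opts.tol * max(obj_prev, 1e-300):
            converged = True
            obj_prev = obj
            break
        obj_prev = obj

    G = X - L - S
    return DecompositionResult(
        low_rank=L, sparse=S, model="godec", iterations=it,
        residual=float(np.linalg.norm(G) / np.sqrt(normX2)),
        converged=converged, noise=G,
        rank_used=_effective_rank(L), card_used=int(np.count_nonzero(S)),
        objective_history=history,
    )
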