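"""Asymmetric pseudo-likelihood direct coupling analysis (plmDCA).

Fits the maximum-entropy pairwise (Potts) sequence model

    P(x) ∝ exp( Σ_i h_i(x_i) + Σ_{i<j} J_ij(x_i, x_j) )

by maximizing, independently for each column i, the ℓ2-penalized
conditional log-likelihood of x_i given the rest of the sequence
(asymmetric pseudo-likelihood), with similarity-based sequence
reweighting.  The two directed estimates of each coupling block are
averaged, blocks are moved to the zero-sum gauge, scored by gap-excluded
Frobenius norms, and corrected with the average-product correction (APC).

Default hyperparameters: lambda_h = 0.01, lambda_J = 0.01, theta = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .msa import AMINO_ACIDS, MsaMatrix

#: DCA state alphabet: gap first, then the 20 amino acids (q = 21)
DCA_ALPHABET: str = "-" + AMINO_ACIDS
GAP_STATE: int = 0

_STATE = {a: i for i, a in enumerate(DCA_ALPHABET)}

#: guard against accidentally launching desk-scale fits on huge inputs
MAX_L_DEFAULT = 400
MAX_N_DEFAULT = 20000


class DcaConvergenceError(RuntimeError):
    """Raised when a per-column fit fails to converge; carries diagnostics."""

    def __init__(self, column: int, grad_norm: float, n_iter: int, message: str):
        self.column = column
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        super().__init__(
            f"plmDCA column {column} did not converge: {message} "
            f"(|grad|={grad_norm:.3g} after {n_iter} iterations)"
        )


@dataclass
class DcaModel:
    """Fitted Potts model parameters and fitting metadata."""

    L: int
    q: int
    h: np.ndarray                  # (L, q)
    J: np.ndarray                  # (L, L, q, q), symmetrized, J[i,i] = 0
    lambda_h: float
    lambda_J: float
    theta: float
    weights: np.ndarray            # (N,)
    objective_histories: list[list[float]] = field(default_factory=list)

    @property
    def M_eff(self) -> float:
        return float(self.weights.sum())


@dataclass
class CouplingScores:
    frobenius: np.ndarray          # (L, L) symmetric, zero diagonal
    apc: np.ndarray                # (L, L) APC-corrected

    def ranked_pairs(self) -> pd.DataFrame:
        L = self.apc.shape[0]
        rows = [(i + 1, j + 1, self.frobenius[i, j], self.apc[i, j])
                for i in range(L) for j in range(i + 1, L)]
        df = pd.DataFrame(rows, columns=["i", "j", "frobenius", "apc_score"])
        return df.sort_values("apc_score", ascending=False, ignore_index=True)


def encode_msa(msa: MsaMatrix) -> np.ndarray:
    """Integer-encode an alignment for DCA: gap = 0, amino acids 1..20.

    Unknown residues (``X``) are treated as gaps.
    """
    X = np.empty((msa.n_seqs, msa.length), dtype=np.int8)
    for s, row in enumerate(msa.rows):
        X[s] = [_STATE.get(ch, GAP_STATE) for ch in row]
    return X


def sequence_weights(msa: MsaMatrix | np.ndarray, theta: float = 0.1) -> np.ndarray:
    """Similarity-based reweighting.

    The weight of sequence s is 1 / |{t : hamming_fraction(s, t) < theta}|,
    with s itself included, so duplicated sequences share one unit of
    weight and M_eff = Σ weights is invariant under duplicating the MSA.
    """
    if not 0 <= theta < 1:
        raise ValueError("theta must lie in [0, 1)")
    X = encode_msa(msa) if isinstance(msa, MsaMatrix) else np.asarray(msa)
    N, L = X.shape
    if theta == 0:
        return np.ones(N)
    neighbors = np.zeros(N, dtype=np.int64)
    # chunked pairwise Hamming comparison to bound memory
    chunk = max(1, int(2e7) // max(N * 1, 1))
    for start in range(0, N, chunk):
        block = X[start:start + chunk]                     # (c, L)
        mism = (block[:, None, :] != X[None, :, :]).sum(axis=2)  # (c, N)
        neighbors[start:start + chunk] = (mism / L < theta).sum(axis=1)
    return 1.0 / neighbors


def _column_objective(params: np.ndarray, Z_other: np.ndarray, xi: np.ndarray,
                      w: np.ndarray, q: int, lambda_h: float, lambda_J: float
                      ) -> tuple[float, np.ndarray]:
    """Penalized negative conditional log-likelihood for one column + gradient.

    ``Z_other``: (N, (L-1)*q) one-hot encoding of all other columns;
    ``xi``: (N,) states of the focal column.
    """
    h = params[:q]
    Jf = params[q:].reshape(-1, q)                          # ((L-1)*q, q)
    logits = h[None, :] + Z_other @ Jf                      # (N, q)
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    Zs = expl.sum(axis=1)
    logp = logits[np.arange(len(xi)), xi] - np.log(Zs)
    P = expl / Zs[:, None]

    nll = -float(w @ logp)
    penalty = lambda_h * float(h @ h) + lambda_J * float((Jf * Jf).sum())

    D = P * w[:, None]
    D[np.arange(len(xi)), xi] -= w
    grad_h = D.sum(axis=0) + 2.0 * lambda_h * h
    grad_J = Z_other.T @ D + 2.0 * lambda_J * Jf
    grad = np.concatenate([grad_h, grad_J.ravel()])
    return nll + penalty, grad


def fit_plmdca(msa: MsaMatrix | np.ndarray, lambda_h: float = 0.01,
               lambda_J: float = 0.01, theta: float = 0.1, q: int = 21,
               tol: float = 1e-5, max_iter: int = 500,
               weights: np.ndarray | None = None,
               allow_large: bool = False) -> DcaModel:
    """Fit the Potts model by asymmetric pseudo-likelihood maximization.

    Each column's conditional model is optimized with L-BFGS-B (analytic
    gradient, projected-gradient tolerance ``tol``); the two directed
    coupling estimates are then averaged: J_ij ← (J_ij + J_jiᵀ)/2.

    Raises :class:`DcaConvergenceError` when a column fails to reach the
    gradient tolerance within ``max_iter`` iterations.  By default refuses
    alignments with L > 400 or N > 20000 (``allow_large`` overrides).
    """
    X = encode_msa(msa) if isinstance(msa, MsaMatrix) else np.asarray(msa)
    N, L = X.shape
    if N < 2 or L < 2:
        raise ValueError("plmDCA requires at least 2 sequences and 2 columns")
    if not allow_large and (L > MAX_L_DEFAULT or N > MAX_N_DEFAULT):
        raise ValueError(
            f"alignment size N={N}, L={L} exceeds the desk-scale guard "
            f"(L<={MAX_L_DEFAULT}, N<={MAX_N_DEFAULT}); pass allow_large=True"
        )
    if X.max() >= q:
        raise ValueError(f"state index {X.max()} out of range for q={q}")
    if weights is None:
        weights = sequence_weights(X, theta)
    w = np.asarray(weights, dtype=float)

    # one-hot encoding of the full alignment, (N, L, q)
    Z = np.zeros((N, L, q))
    Z[np.arange(N)[:, None], np.arange(L)[None, :], X] = 1.0

    h = np.zeros((L, q))
    J_dir = np.zeros((L, L, q, q))  # directed: J_dir[i, j, a, b], row i's model
    histories: list[list[float]] = []

    others_cache = np.arange(L)
    for i in range(L):
        others = others_cache[others_cache != i]
        Z_other = Z[:, others, :].reshape(N, (L - 1) * q)
        xi = X[:, i].astype(np.int64)
        history: list[float] = []

        def cb(params, _state=None):
            val, _ = _column_objective(params, Z_other, xi, w, q,
                                       lambda_h, lambda_J)
            history.append(val)

        x0 = np.zeros(q + (L - 1) * q * q)
        res = minimize(_column_objective, x0, jac=True,
                       args=(Z_other, xi, w, q, lambda_h, lambda_J),
                       method="L-BFGS-B", callback=cb,
                       options={"maxiter": max_iter, "gtol": tol,
                                "ftol": 1e-12, "maxfun": 10 * max_iter})
        grad_norm = float(np.max(np.abs(res.jac)))
        if not res.success and grad_norm > 10 * tol:
            raise DcaConvergenceError(i + 1, grad_norm, res.nit,
                                      res.message if isinstance(res.message, str)
                                      else str(res.message))
        h[i] = res.x[:q]
        Jf = res.x[q:].reshape(L - 1, q, q)
        for k, j in enumerate(others):
            J_dir[i, j] = Jf[k]
        histories.append(history)

    # symmetrize the two directed estimates
    J = np.zeros_like(J_dir)
    for i in range(L):
        for j in range(i + 1, L):
            block = 0.5 * (J_dir[i, j] + J_dir[j, i].T)
            J[i, j] = block
            J[j, i] = block.T
    return DcaModel(L, q, h, J, lambda_h, lambda_J, theta, w, histories)


def zero_sum_gauge_block(block: np.ndarray) -> np.ndarray:
    """Shift a coupling block so its rows and columns each sum to zero."""
    return (block - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True) + block.mean())


def apc(F: np.ndarray) -> np.ndarray:
    """Average-product correction: F_ij − F_i· F_·j / F_··.

    Row/column/grand means are over all entries, so a rank-one matrix maps
    exactly to zero.
    """
    F = np.asarray(F, dtype=float)
    row = F.mean(axis=1)
    grand = F.mean()
    if grand == 0:
        return F.copy()
    return F - np.outer(row, F.mean(axis=0)) / grand


def coupling_scores(model: DcaModel, exclude_gap: bool = True) -> CouplingScores:
    """Gauge-fixed, gap-excluded Frobenius norms with APC correction."""
    L, q = model.L, model.q
    states = slice(1, q) if exclude_gap else slice(0, q)
    F = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = zero_sum_gauge_block(model.J[i, j][states, states])
            F[i, j] = F[j, i] = np.linalg.norm(block)
    scores = apc(F)
    np.fill_diagonal(scores, 0.0)
    scores = 0.5 * (scores + scores.T)
    return CouplingScores(F, scores)
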