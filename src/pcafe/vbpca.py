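"""Feature-dependent variational Bayes PCA (VBPCAFE).

The model is the probabilistic matrix factorisation ``V = B A^T + E`` with
``B`` (features x Q), ``A`` (samples x Q) and i.i.d. Gaussian noise of
variance ``sigma_E^2``.  Gaussian priors are placed on both factors; the
prior variance of the feature scores is *feature-dependent*,

    P(B_iq) ~ exp( - B_iq^2 / (2 C_B^{iq}) ),

so that after the variational updates the learned ``C_B^{iq}`` acts as an
automatic-relevance weight per feature and component: features irrelevant
to component ``q`` have their prior variance driven toward zero.  Feature
extraction reads off the largest ``C_B^{i1}`` (or any other component).

The per-component prior variance of the sample loadings, ``C_A``, is
renormalised to sum to one after every cycle, which suppresses the global
scale divergence the feature-dependent extension would otherwise allow; it
plays the role of a relative component-relevance spectrum.

All updates below are applied in a fixed order (the coordinate updates are
mutually independent, so any order reaches the same fixed points); the
iteration tracks the variational free energy ``F`` and the currently
extracted feature set, stops once that set has been stable for ``patience``
consecutive iterations, and reports the visited state with the smallest
``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import ExpressionMatrix
from .result import FEResult

__all__ = ["VBPCAState", "vbpca_init", "vbpca_update", "free_energy", "vbpca_fit", "vbpcafe_select"]

#: numerical floor for prior variances and the noise variance before inversion;
#: C_B entries of ARD-pruned ("dead") features legitimately approach zero.
FLOOR = 1e-12
RIDGE = 1e-10


@dataclass
class VBPCAState:
    """All variational quantities of the feature-dependent VBPCA model."""

    A_hat: np.ndarray       # (M, Q) posterior-mean sample loadings
    B_hat: np.ndarray       # (N, Q) posterior-mean feature scores
    Sigma_A: np.ndarray     # (Q, Q) shared covariance of the rows of A_hat
    Sigma_B: np.ndarray     # (N, Q, Q) per-feature covariance of B_hat rows
    C_A: np.ndarray         # (Q,) component relevances, positive, sum to 1
    C_B: np.ndarray         # (N, Q) feature-dependent prior variances
    sigma_E2: float         # noise variance > 0
    F: float = np.nan       # free energy of this state
    n_iter: int = 0

    @property
    def Q(self) -> int:
        return self.A_hat.shape[1]

    def copy(self) -> "VBPCAState":
        return VBPCAState(
            self.A_hat.copy(), self.B_hat.copy(), self.Sigma_A.copy(),
            self.Sigma_B.copy(), self.C_A.copy(), self.C_B.copy(),
            float(self.sigma_E2), float(self.F), self.n_iter,
        )


def _safe_inv(mat: np.ndarray) -> np.ndarray:
    """Invert, retrying once with a small ridge if singular."""
    try:
        return np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        eye = np.eye(mat.shape[-1])
        return np.linalg.inv(mat + RIDGE * eye)


def vbpca_init(X: ExpressionMatrix | np.ndarray, Q: int) -> VBPCAState:
    """Initialise from a conventional PCA/SVD factorisation ``X ~ B A^T``.

    ``B`` takes the scaled left singular vectors, ``A`` the (orthonormal)
    right singular vectors; covariances start as small multiples of the
    identity, ``C_A`` uniform, ``C_B`` from its own update rule applied to
    the initial ``B``, and ``sigma_E^2`` from the rank-Q residual.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    N, M = V.shape
    if Q > min(N, M):
        raise ValueError(f"Q={Q} exceeds min(N, M)={min(N, M)}")
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    B = U[:, :Q] * S[:Q]
    A = Vt[:Q].T
    Sigma_A = np.eye(Q) * 1e-6
    Sigma_B = np.tile(np.eye(Q) * 1e-6, (N, 1, 1))
    C_A = np.full(Q, 1.0 / Q)
    C_B = B**2 + np.einsum("iqq->iq", Sigma_B)
    resid = V - B @ A.T
    sigma_E2 = max(float((resid**2).sum() / (N * M)), FLOOR)
    return VBPCAState(A, B, Sigma_A, Sigma_B, C_A, np.maximum(C_B, FLOOR), sigma_E2)


def vbpca_update(state: VBPCAState, X: ExpressionMatrix | np.ndarray) -> VBPCAState:
    """One full update cycle, in the fixed listed order.

    Sigma_A <- sE2 (B^T B + sum_i Sigma_B^i + sE2 C_A^{-1})^{-1}
    A       <- V^T B Sigma_A / sE2
    Sigma_B^i <- sE2 (A^T A + M Sigma_A + sE2 (C_B^i)^{-1})^{-1}
    B_i     <- V_i A Sigma_B^i / sE2
    C_A     <- normalise( ||A_q||^2/M + (Sigma_A)_qq )
    C_B^iq  <- B_iq^2 + (Sigma_B^i)_qq
    sE2     <- (1/NM){ ||V||^2 - 2 tr(V^T B A^T)
                       + tr((A^T A + M Sigma_A)(B^T B + sum_i Sigma_B^i)) }
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    N, M = V.shape
    Q = state.Q
    st = state.copy()
    sE2 = max(st.sigma_E2, FLOOR)
    eye = np.eye(Q)

    SB_sum = st.Sigma_B.sum(axis=0)
    st.Sigma_A = sE2 * _safe_inv(
        st.B_hat.T @ st.B_hat + SB_sum + sE2 * np.diag(1.0 / np.maximum(st.C_A, FLOOR))
    )
    st.A_hat = V.T @ st.B_hat @ st.Sigma_A / sE2

    G = st.A_hat.T @ st.A_hat + M * st.Sigma_A
    inv_arg = G[None, :, :] + sE2 * np.einsum(
        "iq,qp->iqp", 1.0 / np.maximum(st.C_B, FLOOR), eye
    )
    try:
        st.Sigma_B = sE2 * np.linalg.inv(inv_arg)
    except np.linalg.LinAlgError:
        st.Sigma_B = sE2 * np.linalg.inv(inv_arg + RIDGE * eye[None, :, :])
    XA = V @ st.A_hat
    st.B_hat = np.einsum("iq,iqp->ip", XA, st.Sigma_B) / sE2

    C_tilde = (st.A_hat**2).sum(axis=0) / M + np.diag(st.Sigma_A)
    st.C_A = C_tilde / C_tilde.sum()
    st.C_B = st.B_hat**2 + np.einsum("iqq->iq", st.Sigma_B)

    G = st.A_hat.T @ st.A_hat + M * st.Sigma_A
    BtB_S = st.B_hat.T @ st.B_hat + st.Sigma_B.sum(axis=0)
    st.sigma_E2 = max(
        float(
            (
                (V**2).sum()
                - 2.0 * np.einsum("iq,iq->", XA, st.B_hat)
                + np.einsum("qp,pq->", G, BtB_S)
            )
            / (N * M)
        ),
        FLOOR,
    )
    st.n_iter = state.n_iter + 1
    st.F = free_energy(st, V)
    return st


def free_energy(state: VBPCAState, X: ExpressionMatrix | np.ndarray) -> float:
    """Variational free energy of a state (additive constant dropped).

    F = ||V||^2/(2 sE2) + (NM/2) log sE2
        + (M/2) log(|C_A| / |Sigma_A|) + (1/2) sum_i log(|C_B^i| / |Sigma_B^i|)
        + (1/2) sum_i B_i^T (C_B^i)^{-1} B_i
        + (1/2) tr{ C_A^{-1}(A^T A + M Sigma_A) + sum_i (C_B^i)^{-1} Sigma_B^i
                    + sE2^{-1}( -2 A^T V^T B
                                + (A^T A + M Sigma_A)(B^T B + sum_i Sigma_B^i) ) }
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    N, M = V.shape
    st = state
    sE2 = max(st.sigma_E2, FLOOR)
    C_A = np.maximum(st.C_A, FLOOR)
    C_B = np.maximum(st.C_B, FLOOR)
    sign_A, logdet_SA = np.linalg.slogdet(st.Sigma_A)
    signs_B, logdet_SB = np.linalg.slogdet(st.Sigma_B)
    if sign_A <= 0 or (signs_B <= 0).any():
        raise ValueError("covariance matrices must be positive-definite")
    G = st.A_hat.T @ st.A_hat + M * st.Sigma_A
    BtB_S = st.B_hat.T @ st.B_hat + st.Sigma_B.sum(axis=0)
    F = (
        (V**2).sum() / (2.0 * sE2)
        + N * M / 2.0 * np.log(sE2)
        + M / 2.0 * (np.log(C_A).sum() - logdet_SA)
        + 0.5 * (np.log(C_B).sum() - logdet_SB.sum())
        + 0.5 * (st.B_hat**2 / C_B).sum()
        + 0.5 * ((1.0 / C_A) * np.diag(G)).sum()
        + 0.5 * (np.einsum("iqq->iq", st.Sigma_B) / C_B).sum()
        + 0.5 / sE2 * (
            -2.0 * np.einsum("iq,iq->", V @ st.A_hat, st.B_hat)
            + np.einsum("qp,pq->", G, BtB_S)
        )
    )
    return float(F)


def vbpca_fit(
    X: ExpressionMatrix | np.ndarray,
    Q: int = 10,
    max_iter: int = 2000,
    patience: int = 100,
    n_top: int = 10,
    pc: int = 1,
) -> VBPCAState:
    """Fit by iterating the update cycle until the extracted set is stable.

    Tracks the top-``n_top`` set by ``C_B^{i,pc}`` each iteration; declares
    convergence once the set has not changed for ``patience`` consecutive
    iterations (or stops at ``max_iter``).  The *visited state with the
    smallest free energy* is returned, which is the state feature
    extraction should read.
    """
    if max_iter < patience or patience < 1:
        raise ValueError("require max_iter >= patience >= 1")
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    state = vbpca_init(V, Q)
    state.F = free_energy(state, V)
    best = state
    top: frozenset[int] | None = None
    stable = 0
    for _ in range(max_iter):
        state = vbpca_update(state, V)
        if not np.isfinite(state.F):
            raise FloatingPointError(
                f"free energy diverged at iteration {state.n_iter}"
            )
        if state.F < best.F:
            best = state
        new_top = frozenset(np.argsort(-state.C_B[:, pc - 1], kind="stable")[:n_top].tolist())
        if new_top == top:
            stable += 1
            if stable >= patience:
                break
        else:
            stable = 0
            top = new_top
    best.n_iter = state.n_iter
    return best


def vbpcafe_select(state: VBPCAState, q: int = 1, n_top: int = 10) -> FEResult:
    """Extract the ``n_top`` features with the largest ``C_B^{iq}``, descending.

    ``q`` is the 1-based component index; component 1 corresponds to the
    first conventional PC the iteration was initialised from.
    """
    if not 1 <= q <= state.Q:
        raise ValueError(f"component index {q} outside 1..{state.Q}")
    scores = state.C_B[:, q - 1]
    if n_top > scores.shape[0]:
        raise ValueError("n_top exceeds the number of features")
    order = np.argsort(-scores, kind="stable")[:n_top]
    return FEResult(order, scores, "vbpcafe", {"q": q, "n_top": n_top})
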