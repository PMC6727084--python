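"""Shared coordinate-descent pieces for the marginal and joint solvers.

Both solvers minimize, per coordinate, a scalar problem

    0.5 * a * theta^2 - u * theta + rho_MCP(|theta|; lambda, gamma)

where the fusion penalty contributes frozen-state quadratic/linear terms to
(a, u).  The fusion state (sign-agreement indicators for magnitude fusion,
smoothing denominators for sign fusion) is refrozen once per full sweep, so
each sweep performs exact CD on a fixed surrogate objective.
"""

from __future__ import annotations

import numpy as np

from .penalties import FusionState


def fusion_cd_terms(coef: np.ndarray, k: int, state: FusionState,
                    lam: float, fusion_type: str):
    """Quadratic (a) and linear (u) fusion contributions for cohort ``k``.

    ``coef`` is the current p x K coefficient matrix (other cohorts' values
    are used as-is; they are fixed while cohort k's coordinates update).
    Returns arrays of shape (p,).  Derived from the ordered-pair objective
    (lam/2) * sum_{k' != k} rho(eta_k, eta_k') summed over both directions.
    """
    p, K = coef.shape
    if lam == 0.0 or fusion_type == "none":
        z = np.zeros(p)
        return z, z
    others = [kk for kk in range(K) if kk != k]
    if fusion_type == "magnitude":
        s_k = state.s[:, k, others]  # (p, K-1)
        a = lam * ((K - 1) + s_k.sum(axis=1))
        u = 2.0 * lam * np.einsum("jm,jm->j", s_k, coef[:, others])
        return a, u
    if fusion_type == "sign":
        d = state.d
        a = 2.0 * lam * (K - 1) / d[:, k] ** 2
        u = (2.0 * lam / d[:, k]) * (coef[:, others] / d[:, others]).sum(axis=1)
        return a, u
    raise ValueError(f"unknown fusion type {fusion_type!r}")


def fusion_surrogate_value(coef: np.ndarray, state: FusionState,
                           lam: float, fusion_type: str) -> np.ndarray:
    """Frozen-state fusion surrogate, per gene row: (lam/2) * ordered-pair sum.

    Returns shape (p,).
    """
    p, K = coef.shape
    if lam == 0.0 or fusion_type == "none":
        return np.zeros(p)
    if fusion_type == "magnitude":
        diff = coef[:, :, None] - state.s * coef[:, None, :]
        idx = np.arange(K)
        diff[:, idx, idx] = 0.0
        return 0.5 * lam * np.sum(diff**2, axis=(1, 2))
    if fusion_type == "sign":
        r = coef / state.d
        diff = r[:, :, None] - r[:, None, :]
        return 0.5 * lam * np.sum(diff**2, axis=(1, 2))
    raise ValueError(f"unknown fusion type {fusion_type!r}")
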