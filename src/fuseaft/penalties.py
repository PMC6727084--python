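"""Penalty primitives.

Minimax concave penalty (MCP) value and its exact univariate proximal
operator, the two across-cohort fusion penalties (magnitude-based and
sign-based), and the smoothed sign surrogate used by the coordinate-descent
solvers.

Conventions
-----------
* Sign(0) = 0 throughout.
* Fusion sums run over *ordered* cohort pairs (k, k') with k' != k, so the
  lambda/2 prefactor in the objectives yields weight lambda per unordered
  pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvexityError

__all__ = [
    "PenaltySpec",
    "FusionState",
    "mcp_value",
    "mcp_prox",
    "magnitude_fusion_value",
    "sign_fusion_value",
    "smooth_sign",
    "fusion_value",
]

FUSION_TYPES = ("magnitude", "sign", "none")


@dataclass
class PenaltySpec:
    """Tuning parameters of one fit.

    ``lambda_sparsity`` is the MCP threshold (lambda1 marginal / lambda3
    joint); ``lambda_fusion`` weights the across-cohort fusion penalty
    (lambda2 / lambda4).  ``gamma`` is the MCP concavity parameter and
    ``tau`` the sign-smoothing constant of the differentiable sign
    surrogate.
    """

    fusion_type: str = "magnitude"
    lambda_sparsity: float = 0.1
    lambda_fusion: float = 0.0
    gamma: float = 3.0
    tau: float = 1e-2

    def __post_init__(self) -> None:
        if self.fusion_type not in FUSION_TYPES:
            raise ValueError(f"fusion_type must be one of {FUSION_TYPES}")
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.lambda_sparsity < 0 or self.lambda_fusion < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class FusionState:
    """Per-sweep frozen quantities of the fusion surrogate.

    For magnitude fusion, ``s`` holds the sign-agreement indicators
    s[j, k, k'] = I(Sgn(coef[j,k]) == Sgn(coef[j,k'])) frozen at the sweep's
    starting iterate.  For sign fusion, ``d`` holds the frozen smoothing
    denominators sqrt(coef^2 + tau).
    """

    s: np.ndarray | None = None
    d: np.ndarray | None = None

    @classmethod
    def freeze(cls, coef: np.ndarray, fusion_type: str, tau: float) -> "FusionState":
        coef = np.atleast_2d(coef)
        if fusion_type == "magnitude":
            sg = np.sign(coef)
            s = (sg[:, :, None] == sg[:, None, :]).astype(float)
            return cls(s=s)
        if fusion_type == "sign":
            return cls(d=np.sqrt(coef**2 + tau))
        return cls()


# ---------------------------------------------------------------------------
# MCP
# ---------------------------------------------------------------------------


def mcp_value(v, lam, gamma):
    """MCP rho(v; lam, gamma) = lam * int_0^{|v|} (1 - x/(lam*gamma))_+ dx.

    Equals ``lam|v| - v^2/(2 gamma)`` for ``|v| <= gamma lam`` and saturates
    at ``gamma lam^2 / 2`` beyond.  Vectorized in ``v``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    v = np.asarray(v, dtype=float)
    av = np.abs(v)
    out = np.where(
        av <= gamma * lam, lam * av - av**2 / (2.0 * gamma), 0.5 * gamma * lam**2
    )
    return out if out.ndim else float(out)


def mcp_prox(u, a, lam, gamma):
    """Exact minimizer of ``0.5*a*theta^2 - u*theta + rho_MCP(|theta|)``.

    Requires ``a > 1/gamma`` (strict convexity of the scalar subproblem).
    Vectorized in ``u`` and ``a``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a <= 1.0 / gamma):
        raise ConvexityError(
            "scalar MCP subproblem non-convex (a <= 1/gamma); increase gamma"
        )
    soft = np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
    inner = soft / (a - 1.0 / gamma)
    out = np.where(np.abs(u) <= a * gamma * lam, inner, u / a)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fusion penalties (exact values, used by the objectives)
# ---------------------------------------------------------------------------


def magnitude_fusion_value(coef_row) -> float:
    """Ordered-pair sum  sum_{k' != k} (eta_k - s_kk' * eta_k')^2  with
    s_kk' = I(Sgn(eta_k) == Sgn(eta_k'))."""
    eta = np.asarray(coef_row, dtype=float)
    sg = np.sign(eta)
    s = (sg[:, None] == sg[None, :]).astype(float)
    diff = eta[:, None] - s * eta[None, :]
    np.fill_diagonal(diff, 0.0)
    return float(np.sum(diff**2))


def sign_fusion_value(coef_row) -> float:
    """Ordered-pair sum  sum_{k' != k} (Sgn(eta_k) - Sgn(eta_k'))^2."""
    sg = np.sign(np.asarray(coef_row, dtype=float))
    diff = sg[:, None] - sg[None, :]
    return float(np.sum(diff**2))


def fusion_value(coef_row, fusion_type: str) -> float:
    if fusion_type == "magnitude":
        return magnitude_fusion_value(coef_row)
    if fusion_type == "sign":
        return sign_fusion_value(coef_row)
    if fusion_type == "none":
        return 0.0
    raise ValueError(f"unknown fusion type {fusion_type!r}")


def smooth_sign(v, tau: float):
    """Differentiable sign surrogate v / sqrt(v^2 + tau); odd, in (-1, 1)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    v = np.asarray(v, dtype=float)
    out = v / np.sqrt(v**2 + tau)
    return out if out.ndim else float(out)
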