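"""Marginal integrative solver: one gene at a time, K cohorts jointly.

For each gene j the objective is

    sum_k (1/(2 n_k)) sum_i w_ik (y_ik - alpha_jk - x_ijk eta_jk)^2
    + sum_k rho_MCP(|eta_jk|; lambda1, gamma)
    + (lambda2/2) sum_{k' != k} rho(eta_jk, eta_jk')

minimized by coordinate descent over the K cohort slopes.  Intercepts are
absorbed by KM-weighted centering and recovered afterwards.  Because the
design is standardized to unit weighted mean square, the loss contributes
curvature exactly 1 per coordinate and the loss linear term is the constant
weighted inner product R[j, k]; a full fit of all p genes is therefore
vectorized across genes (genes are independent).

Penalties act on standardized-scale coefficients; reported ``eta``/``alpha``
are mapped back to the original data scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cd import fusion_cd_terms, fusion_surrogate_value
from .datasets import MultiCancerData, cohort_list, weighted_standardize
from .exceptions import DataFormatError
from .penalties import FusionState, PenaltySpec, fusion_value, mcp_prox, mcp_value

__all__ = ["MarginalFit", "marginal_objective", "fit_marginal_gene", "fit_marginal_all"]


@dataclass
class MarginalFit:
    """Result of the marginal integrative analysis."""

    eta: np.ndarray          # (p, K) slopes, original scale
    alpha: np.ndarray        # (p, K) intercepts, original scale
    eta_std: np.ndarray      # (p, K) slopes on the standardized scale
    objective: np.ndarray    # (p,) final internal (standardized) objective
    iterations: np.ndarray   # (p,) sweep at which each gene first converged
    converged: np.ndarray    # (p,) bool
    spec: PenaltySpec
    gene_ids: list
    cancer_ids: list
    surrogate_trace: list | None = None

    @property
    def selected(self) -> np.ndarray:
        """Boolean (p, K): gene identified for cohort k iff eta_jk != 0."""
        return self.eta != 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.eta, index=self.gene_ids, columns=self.cancer_ids)


def marginal_objective(gene_index: int, eta_row, alpha_row,
                       data: MultiCancerData, weights, spec: PenaltySpec) -> float:
    """Direct evaluation of the marginal objective for one gene.

    Evaluated on the data exactly as passed (no internal standardization);
    shapes must conform.
    """
    eta_row = np.asarray(eta_row, dtype=float)
    alpha_row = np.asarray(alpha_row, dtype=float)
    dsets = cohort_list(data)
    K = len(dsets)
    if eta_row.shape != (K,) or alpha_row.shape != (K,):
        raise DataFormatError(f"eta/alpha rows must have length K={K}")
    loss = 0.0
    for k, ds in enumerate(dsets):
        w = weights[k].w
        r = ds.y - alpha_row[k] - ds.X[:, gene_index] * eta_row[k]
        loss += 0.5 / ds.n * float(w @ (r**2))
    pen = float(np.sum(mcp_value(np.abs(eta_row), spec.lambda_sparsity, spec.gamma)))
    fus = 0.5 * spec.lambda_fusion * fusion_value(eta_row, spec.fusion_type)
    return loss + pen + fus


def _standardize_all(dsets, weights):
    """Standardize every cohort; return (R, const, records, retained).

    R[j, k] = (1/n_k) sum_i w_ik x_std_ijk y_c_ik  (the constant loss linear
    term of each coordinate), const[k] = (1/(2 n_k)) sum_i w_ik y_c_ik^2.
    """
    p, K = dsets[0].p, len(dsets)
    R = np.empty((p, K))
    const = np.empty(K)
    records, retained = [], np.empty((p, K), dtype=bool)
    std_sets = []
    for k, ds in enumerate(dsets):
        std, rec = weighted_standardize(ds, weights[k])
        wv = weights[k].w
        R[:, k] = (wv * std.y) @ std.X / ds.n
        const[k] = 0.5 / ds.n * float(wv @ (std.y**2))
        records.append(rec)
        retained[:, k] = rec.retained
        std_sets.append(std)
    return R, const, records, retained, std_sets


def _true_objective_rows(eta, R, const, spec):
    """Per-gene value of the exact objective on the standardized problem."""
    lam1, lam2 = spec.lambda_sparsity, spec.lambda_fusion
    loss = (const[None, :] - R * eta + 0.5 * eta**2).sum(axis=1)
    pen = mcp_value(np.abs(eta), lam1, spec.gamma).sum(axis=1)
    if lam2 == 0.0 or spec.fusion_type == "none":
        return loss + pen
    if spec.fusion_type == "magnitude":
        sg = np.sign(eta)
        s = (sg[:, :, None] == sg[:, None, :]).astype(float)
        diff = eta[:, :, None] - s * eta[:, None, :]
        idx = np.arange(eta.shape[1])
        diff[:, idx, idx] = 0.0
        fus = 0.5 * lam2 * np.sum(diff**2, axis=(1, 2))
    else:
        sg = np.sign(eta)
        diff = sg[:, :, None] - sg[:, None, :]
        fus = 0.5 * lam2 * np.sum(diff**2, axis=(1, 2))
    return loss + pen + fus


def _cd_marginal(R, const, retained, spec, tol, max_iter, monitor,
                 eta0=None):
    """Vectorized-across-genes CD on the standardized problem."""
    p, K = R.shape
    lam1, lam2 = spec.lambda_sparsity, spec.lambda_fusion
    eta = np.zeros((p, K)) if eta0 is None else np.array(eta0, dtype=float)
    iterations = np.full(p, max_iter, dtype=int)
    done = np.zeros(p, dtype=bool)
    trace = [] if monitor else None

    def surrogate(e, state):
        loss = (const[None, :] - R * e + 0.5 * e**2).sum(axis=1)
        pen = mcp_value(np.abs(e), lam1, spec.gamma).sum(axis=1)
        fus = fusion_surrogate_value(e, state, lam2, spec.fusion_type)
        return loss + pen + fus

    for it in range(1, max_iter + 1):
        state = FusionState.freeze(eta, spec.fusion_type, spec.tau)
        if monitor:
            before = surrogate(eta, state)
        eta_old = eta.copy()
        for k in range(K):
            a_f, u_f = fusion_cd_terms(eta, k, state, lam2, spec.fusion_type)
            new = mcp_prox(R[:, k] + u_f, 1.0 + a_f, lam1, spec.gamma)
            new[~retained[:, k]] = 0.0
            eta[:, k] = new
        if monitor:
            trace.append((surrogate(eta_old, state), surrogate(eta, state)))
        change = np.max(np.abs(eta - eta_old), axis=1)
        scale = 1.0 + np.max(np.abs(eta), axis=1)
        ok = change < tol * scale
        newly = ok & ~done
        iterations[newly] = it
        done |= ok
        if ok.all():
            break
    return eta, iterations, done, trace


def _polish_marginal(eta, R, const, retained, spec, tol, max_iter):
    """Deterministic drop-restarts around CD's fixed point.

    The fused objective is nonconvex, and CD from zero can keep a weak
    cohort's coefficient nonzero because fusion couples it to a strong one
    while the global optimum drops it.  For each cohort, restart CD from the
    converged point with that cohort's coefficient zeroed and keep the
    candidate whenever it improves the exact objective.
    """
    best_obj = _true_objective_rows(eta, R, const, spec)
    K = eta.shape[1]
    for k in range(K):
        nonzero = eta[:, k] != 0.0
        if not nonzero.any():
            continue
        start = eta.copy()
        start[:, k] = 0.0
        cand, _, _, _ = _cd_marginal(R, const, retained, spec, tol,
                                     max_iter, False, eta0=start)
        cand_obj = _true_objective_rows(cand, R, const, spec)
        better = cand_obj < best_obj - 1e-12
        eta[better] = cand[better]
        best_obj[better] = cand_obj[better]
    return eta


def fit_marginal_all(data: MultiCancerData, weights, spec: PenaltySpec,
                     tol: float = 1e-4, max_iter: int = 500,
                     monitor: bool = False, polish: bool = True) -> MarginalFit:
    """Fit the marginal integrative model for every gene.

    The same (lambda1, lambda2) apply to all genes.  Genes are independent,
    so the per-gene CD sweeps run vectorized across genes.  ``polish``
    enables deterministic per-cohort drop-restarts that guard against the
    local minima the fusion coupling can create.
    """
    dsets = cohort_list(data)
    for ds in dsets:
        ds.require_canonical()
    R, const, records, retained, _ = _standardize_all(dsets, weights)
    eta_std, iterations, done, trace = _cd_marginal(
        R, const, retained, spec, tol, max_iter, monitor
    )
    if polish and spec.lambda_fusion > 0 and spec.fusion_type != "none":
        eta_std = _polish_marginal(eta_std, R, const, retained, spec, tol,
                                   max_iter)
    p, K = eta_std.shape
    eta = np.zeros((p, K))
    alpha = np.zeros((p, K))
    for k, rec in enumerate(records):
        r = rec.retained
        eta[r, k] = eta_std[r, k] / rec.x_scale[r]
        alpha[:, k] = rec.y_mean - rec.x_mean * eta[:, k]
    state = FusionState.freeze(eta_std, spec.fusion_type, spec.tau)
    loss = (const[None, :] - R * eta_std + 0.5 * eta_std**2).sum(axis=1)
    pen = mcp_value(np.abs(eta_std), spec.lambda_sparsity, spec.gamma).sum(axis=1)
    fus = np.array(
        [0.5 * spec.lambda_fusion * fusion_value(eta_std[j], spec.fusion_type)
         for j in range(p)]
    )
    return MarginalFit(
        eta=eta,
        alpha=alpha,
        eta_std=eta_std,
        objective=loss + pen + fus,
        iterations=iterations,
        converged=done,
        spec=spec,
        gene_ids=list(dsets[0].gene_ids),
        cancer_ids=[ds.cancer_id for ds in dsets],
        surrogate_trace=trace,
    )


def fit_marginal_gene(gene_index: int, data: MultiCancerData, weights,
                      spec: PenaltySpec, tol: float = 1e-4,
                      max_iter: int = 500, seed=None):
    """Fit a single gene; returns ``(eta_row, alpha_row, diagnostics)``.

    ``seed`` is accepted for interface symmetry; the solver is deterministic
    (zero initialization, fixed cohort order) and ignores it.
    """
    sub = [
        type(ds)(
            cancer_id=ds.cancer_id,
            gene_ids=[ds.gene_ids[gene_index]],
            X=ds.X[:, [gene_index]],
            y=ds.y,
            delta=ds.delta,
            canonical=ds.canonical,
        )
        for ds in cohort_list(data)
    ]
    fit = fit_marginal_all(sub, weights, spec, tol=tol, max_iter=max_iter)
    diagnostics = {
        "iterations": int(fit.iterations[0]),
        "converged": bool(fit.converged[0]),
        "objective": float(fit.objective[0]),
        "eta_std": fit.eta_std[0].copy(),
    }
    return fit.eta[0], fit.alpha[0], diagnostics
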