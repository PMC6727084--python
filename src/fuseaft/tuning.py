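"""Tuning-parameter selection: lambda_max, CV and BIC-type selection.

The grid is built from ``lambda_max`` (smallest sparsity penalty at which
the all-zero solution is stationary when the fusion weight is zero) with
log-spaced sparsity values and relative fusion multipliers.  Two selectors
are offered:

* :func:`select_lambdas_cv` — V-fold cross-validation, folds drawn within
  each cohort stratified by event status, scoring the KM-weighted squared
  prediction error on held-out folds (held-out KM weights recomputed on the
  held-out subsample).
* :func:`select_lambdas_bic` — a faster BIC-type criterion
  ``sum_k [ n_k * log(wRSS_k) + log(n_k) * df_k ]`` computed on the full
  data along the path (Gaussian BIC with unknown variance; robust to the
  outcome scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .datasets import CancerDataset, cohort_list, weighted_standardize
from .exceptions import DegenerateWeightsError, StratificationError
from .joint import fit_joint
from .kmweights import compute_km_weights
from .marginal import _standardize_all, fit_marginal_all
from .penalties import PenaltySpec

__all__ = [
    "LambdaGrid",
    "TuningResult",
    "lambda_max",
    "build_grid",
    "select_lambdas_cv",
    "select_lambdas_bic",
]


@dataclass
class LambdaGrid:
    """Grid specification: log-spaced sparsity path x fusion multipliers."""

    n_sparsity: int = 25
    min_ratio: float = 0.05
    fusion_multipliers: tuple = (0.0, 0.1, 1.0, 10.0)


@dataclass
class TuningResult:
    pairs: list                 # [(lambda_sparsity, lambda_fusion), ...]
    mean_loss: np.ndarray
    se_loss: np.ndarray
    selected: tuple
    folds: dict = field(default_factory=dict)   # cohort label -> fold ids
    criterion: str = "cv"

    @property
    def selected_index(self) -> int:
        return self.pairs.index(self.selected)


def lambda_max(data, weights) -> float:
    """Smallest sparsity penalty making the all-zero fit stationary
    (fusion weight zero): max over (j, k) of |(1/n_k) sum_i w x_std y_c|."""
    dsets = cohort_list(data)
    R, _, _, retained, _ = _standardize_all(dsets, weights)
    vals = np.abs(R)[retained]
    return float(vals.max()) if vals.size else 0.0


def build_grid(lmax: float, grid: LambdaGrid) -> list:
    """Ordered candidate pairs; the sparsity path runs high to low so that
    warm starts traverse it naturally."""
    if lmax <= 0:
        path = np.array([0.0])
    else:
        path = np.geomspace(lmax, grid.min_ratio * lmax, grid.n_sparsity)
    pairs = []
    for m in grid.fusion_multipliers:
        for lam1 in path:
            pairs.append((float(lam1), float(m * lam1)))
    return pairs


def _fit_path(dsets, weights, spec_template, pairs, model, tol, max_iter):
    """Fit every grid pair; warm-start the joint solver along each
    descending-sparsity run.  Returns the list of fits."""
    fits = []
    prev_beta = None
    prev_lam1 = np.inf
    for lam1, lam2 in pairs:
        spec = dc_replace(
            spec_template, lambda_sparsity=lam1, lambda_fusion=lam2
        )
        if model == "marginal":
            fits.append(fit_marginal_all(dsets, weights, spec,
                                         tol=tol, max_iter=max_iter))
        else:
            if lam1 > prev_lam1:      # new multiplier run: cold start
                prev_beta = None
            fit = fit_joint(dsets, weights, spec, tol=tol, max_iter=max_iter,
                            beta_init=prev_beta)
            prev_beta = fit.beta_std.copy()
            fits.append(fit)
        prev_lam1 = lam1
    return fits


def _select(pairs, mean_loss):
    """Minimal mean loss; ties resolved toward larger sparsity then larger
    fusion penalties."""
    best = None
    for i, pair in enumerate(pairs):
        key = (mean_loss[i], -pair[0], -pair[1])
        if best is None or key < best[0]:
            best = (key, pair)
    return best[1]


def _stratified_folds(dsets, V, rng):
    folds = {}
    for ds in dsets:
        if int(ds.delta.sum()) < V:
            raise StratificationError(
                f"{ds.cancer_id}: fewer than V={V} events; cannot stratify"
            )
        ids = np.empty(ds.n, dtype=int)
        for val in (1, 0):
            idx = np.flatnonzero(ds.delta == val)
            idx = rng.permutation(idx)
            ids[idx] = np.arange(idx.size) % V
        folds[ds.cancer_id] = ids
    return folds


def _canonical_subset(ds: CancerDataset, idx: np.ndarray) -> CancerDataset:
    """Row subset of a canonical dataset; ascending index order preserves
    both the sort and the events-first tie rule."""
    idx = np.sort(np.asarray(idx))
    sub = ds.subset_rows(idx)
    sub.canonical = True
    return sub


def _prediction_loss_marginal(fit, test_sets, test_weights) -> float:
    loss = 0.0
    for k, ds in enumerate(test_sets):
        w = test_weights[k].w
        E = (ds.y[:, None] - fit.alpha[:, k][None, :]
             - ds.X * fit.eta[:, k][None, :])
        loss += 0.5 / ds.n * float((w[:, None] * E**2).sum())
    return loss


def _prediction_loss_joint(fit, test_sets, test_weights) -> float:
    loss = 0.0
    for k, ds in enumerate(test_sets):
        r = ds.y - fit.alpha[k] - ds.X @ fit.beta[:, k]
        loss += 0.5 / ds.n * float(test_weights[k].w @ (r**2))
    return loss


def select_lambdas_cv(data, weights, spec_template: PenaltySpec,
                      grid_spec: LambdaGrid | None = None, V: int = 5,
                      seed: int = 0, model: str = "marginal",
                      tol: float = 1e-4, max_iter: int = 500,
                      pairs=None) -> TuningResult:
    """Pick (lambda_sparsity, lambda_fusion) by stratified V-fold CV.

    ``pairs`` overrides the grid with an explicit candidate list.
    """
    dsets = cohort_list(data)
    for ds in dsets:
        ds.require_canonical()
    grid_spec = grid_spec or LambdaGrid()
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(dsets, V, rng)
    if pairs is None:
        pairs = build_grid(lambda_max(dsets, weights), grid_spec)
    pairs = [tuple(p) for p in pairs]

    losses = np.empty((V, len(pairs)))
    for v in range(V):
        train_sets, test_sets = [], []
        for ds in dsets:
            ids = folds[ds.cancer_id]
            train_sets.append(_canonical_subset(ds, np.flatnonzero(ids != v)))
            test_sets.append(_canonical_subset(ds, np.flatnonzero(ids == v)))
        train_w = [compute_km_weights(ds) for ds in train_sets]
        test_w = [compute_km_weights(ds) for ds in test_sets]
        for tw, ds in zip(test_w, test_sets):
            if tw.total_mass <= 0:
                raise DegenerateWeightsError(
                    f"{ds.cancer_id}: held-out fold has no events"
                )
        fits = _fit_path(train_sets, train_w, spec_template, pairs,
                         model, tol, max_iter)
        score = (_prediction_loss_marginal if model == "marginal"
                 else _prediction_loss_joint)
        losses[v] = [score(f, test_sets, test_w) for f in fits]

    mean_loss = losses.mean(axis=0)
    se_loss = losses.std(axis=0, ddof=1) / np.sqrt(V)
    return TuningResult(
        pairs=pairs,
        mean_loss=mean_loss,
        se_loss=se_loss,
        selected=_select(pairs, mean_loss),
        folds=folds,
        criterion="cv",
    )


def _bic_marginal(fit, dsets, weights) -> float:
    """Support-refit Gaussian BIC summed over all marginal models.

    Penalized estimates are shrunken, which distorts the in-sample RSS along
    the path differently for different fusion weights; the BIC is therefore
    evaluated on the *unpenalized refit* of each selected (gene, cohort)
    pair, so that it scores supports rather than shrinkage.  On the
    standardized scale the single-covariate refit slope is the weighted
    inner product R and the refit wRSS has the closed form W0 - n R^2.
    """
    total = 0.0
    for k, ds in enumerate(dsets):
        std, rec = weighted_standardize(ds, weights[k])
        w = weights[k].w
        n = ds.n
        W0 = float(w @ (std.y**2))
        R = (w * std.y) @ std.X / n
        sel = fit.eta[:, k] != 0
        wrss = np.full(std.p, W0)
        wrss[sel] = W0 - n * R[sel] ** 2
        wrss = np.maximum(wrss, 1e-300)
        total += float(np.sum(n * np.log(wrss) + np.log(n) * sel))
    return total


def _bic_joint(fit, dsets, weights) -> float:
    """Support-refit Gaussian BIC for the joint model (see _bic_marginal)."""
    total = 0.0
    for k, ds in enumerate(dsets):
        std, rec = weighted_standardize(ds, weights[k])
        w = weights[k].w
        n = ds.n
        sel = np.flatnonzero(fit.beta[:, k])
        if sel.size:
            sw = np.sqrt(w)
            A = sw[:, None] * std.X[:, sel]
            b = sw * std.y
            coef, *_ = np.linalg.lstsq(A, b, rcond=None)
            r = b - A @ coef
            wrss = float(r @ r)
        else:
            wrss = float(w @ (std.y**2))
        wrss = max(wrss, 1e-300)
        total += n * np.log(wrss) + np.log(n) * sel.size
    return total


def select_lambdas_bic(data, weights, spec_template: PenaltySpec,
                       grid_spec: LambdaGrid | None = None,
                       model: str = "marginal", tol: float = 1e-4,
                       max_iter: int = 500, return_fits: bool = False):
    """Pick (lambda_sparsity, lambda_fusion) by the BIC-type criterion on the
    full data; much faster than CV for simulation studies."""
    dsets = cohort_list(data)
    grid_spec = grid_spec or LambdaGrid()
    pairs = build_grid(lambda_max(dsets, weights), grid_spec)
    fits = _fit_path(dsets, weights, spec_template, pairs, model, tol, max_iter)
    scorer = _bic_marginal if model == "marginal" else _bic_joint
    scores = np.array([scorer(f, dsets, weights) for f in fits])
    result = TuningResult(
        pairs=pairs,
        mean_loss=scores,
        se_loss=np.zeros_like(scores),
        selected=_select(pairs, scores),
        criterion="bic",
    )
    if return_fits:
        return result, fits
    return result
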