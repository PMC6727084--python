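"""Multi-cohort expression + survival data model.

A :class:`CancerDataset` holds one cohort's expression matrix together with
(log) observed survival times and event indicators.  Datasets are *canonical*
once times have been log-transformed and rows sorted ascending by observed
time, with events preceding censorings at ties; the weighted-least-squares
machinery downstream requires this ordering.

Loading understands two tab-separated expression dialects:

* genes-in-rows (cBioPortal RNA-seq V2 export: first column gene symbol,
  remaining columns one per sample), and
* samples-in-rows (first column sample ID, remaining columns one per gene).

Clinical tables are tab-separated with configurable sample-ID, overall
survival (months) and status columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataFormatError,
    DegenerateWeightsError,
    EmptyIntersectionError,
    EmptyJoinError,
    NonPositiveTimeError,
    NotCanonicalError,
)

__all__ = [
    "CancerDataset",
    "MultiCancerData",
    "StandardizationRecord",
    "load_cancer_dataset",
    "load_panel",
    "canonicalize",
    "align_genes",
    "weighted_standardize",
    "DEFAULT_STATUS_MAP",
]

#: Default mapping from clinical status strings to event indicators.
#: cBioPortal exports use either bare labels or "<code>:<label>" composites.
DEFAULT_STATUS_MAP: Mapping[str, int] = {
    "DECEASED": 1,
    "LIVING": 0,
    "1:DECEASED": 1,
    "0:LIVING": 0,
    "1": 1,
    "0": 0,
}


@dataclass
class CancerDataset:
    """One cohort: expression matrix plus right-censored survival outcome.

    Attributes
    ----------
    cancer_id : str
        Short cohort label, e.g. ``"BRCA"``.
    gene_ids : list of str
        Ordered gene symbols; columns of ``X``.
    X : ndarray of shape (n, p)
        Expression values.
    y : ndarray of shape (n,)
        Observed times.  Raw months before :func:`canonicalize`, natural-log
        months afterwards.
    delta : ndarray of shape (n,)
        Event indicators in {0, 1}; 1 = death observed.
    canonical : bool
        True once times are logged and rows sorted (events first at ties).
    """

    cancer_id: str
    gene_ids: list
    X: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    canonical: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.delta = np.asarray(self.delta, dtype=int)
        if self.X.ndim != 2:
            raise DataFormatError("X must be a 2-D samples x genes matrix")
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.delta.shape != (n,):
            raise DataFormatError(
                f"y/delta length must match X rows (n={n}); got "
                f"{self.y.shape[0]} and {self.delta.shape[0]}"
            )
        if len(self.gene_ids) != self.X.shape[1]:
            raise DataFormatError("gene_ids length must match X columns")
        if not np.isfinite(self.X).all():
            raise DataFormatError("X contains missing/non-finite values")
        if not np.isfinite(self.y).all():
            raise DataFormatError("y contains missing/non-finite values")
        if not np.isin(self.delta, (0, 1)).all():
            raise DataFormatError("delta must contain only 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def require_canonical(self) -> None:
        if not self.canonical:
            raise NotCanonicalError(
                f"dataset {self.cancer_id!r} must be canonicalized first"
            )

    def subset_rows(self, idx: np.ndarray) -> "CancerDataset":
        """Row subset (e.g. a CV fold).  Result is *not* marked canonical."""
        idx = np.asarray(idx)
        return CancerDataset(
            cancer_id=self.cancer_id,
            gene_ids=list(self.gene_ids),
            X=self.X[idx],
            y=self.y[idx],
            delta=self.delta[idx],
            canonical=False,
        )

    @classmethod
    def from_log_times(
        cls,
        cancer_id: str,
        gene_ids: Sequence[str],
        X: np.ndarray,
        log_times: np.ndarray,
        delta: np.ndarray,
    ) -> "CancerDataset":
        """Build a canonical dataset from already log-scale times.

        Used by the simulation module, which generates log event times
        directly rather than months.
        """
        ds = cls(cancer_id, list(gene_ids), X, log_times, delta)
        order = np.lexsort((-ds.delta, ds.y))
        return cls(
            cancer_id,
            list(gene_ids),
            ds.X[order],
            ds.y[order],
            ds.delta[order],
            canonical=True,
        )


@dataclass
class MultiCancerData:
    """K cohorts sharing an identical, identically ordered gene list."""

    datasets: list

    def __post_init__(self) -> None:
        if len(self.datasets) < 2:
            raise DataFormatError("MultiCancerData requires K >= 2 cohorts")
        ref = self.datasets[0].gene_ids
        for ds in self.datasets[1:]:
            if list(ds.gene_ids) != list(ref):
                raise DataFormatError(
                    f"gene_ids of {ds.cancer_id!r} differ from "
                    f"{self.datasets[0].cancer_id!r}"
                )

    @property
    def K(self) -> int:
        return len(self.datasets)

    @property
    def p(self) -> int:
        return self.datasets[0].p

    @property
    def gene_ids(self) -> list:
        return list(self.datasets[0].gene_ids)

    @property
    def cancer_ids(self) -> list:
        return [ds.cancer_id for ds in self.datasets]

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, k):
        return self.datasets[k]


@dataclass
class StandardizationRecord:
    """Weighted moments needed to undo standardization.

    ``x_scale`` is the square root of the KM-weighted mean square of the
    centered column (weighted by w/n rather than w/sum(w), matching the loss
    normalization); degenerate columns carry ``scale = nan`` and
    ``retained = False``.
    """

    y_mean: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    retained: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = np.isfinite(self.x_scale) & (self.x_scale > 0)

    def coef_to_original(self, coef_std: np.ndarray) -> np.ndarray:
        """Map standardized-scale slopes back to the original data scale."""
        out = np.zeros_like(np.asarray(coef_std, dtype=float))
        r = self.retained
        out[r] = np.asarray(coef_std)[r] / self.x_scale[r]
        return out

    def intercept(self, coef_orig: np.ndarray) -> float:
        return float(self.y_mean - self.x_mean @ coef_orig)


def cohort_list(data) -> list:
    """Normalize a MultiCancerData or plain sequence of cohorts to a list.

    Solvers accept either; a single-cohort list is allowed there (the fusion
    term is then empty) even though :class:`MultiCancerData` itself requires
    K >= 2.
    """
    dsets = list(data)
    if not dsets:
        raise DataFormatError("no cohorts given")
    ref = list(dsets[0].gene_ids)
    for ds in dsets[1:]:
        if list(ds.gene_ids) != ref:
            raise DataFormatError(f"gene_ids of {ds.cancer_id!r} differ")
    return dsets


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_GENE_ROW_HEADERS = {
    "hugo_symbol",
    "gene",
    "gene_id",
    "gene_symbol",
    "symbol",
}


def _read_expression(path, orientation: str) -> pd.DataFrame:
    """Return a samples x genes DataFrame indexed by sample ID."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expression table needs >= 2 columns")
    first = str(df.columns[0]).strip().lower()
    if orientation == "auto":
        orientation = (
            "genes_by_samples" if first in _GENE_ROW_HEADERS else "samples_by_genes"
        )
    if orientation == "genes_by_samples":
        df = df.set_index(df.columns[0])
        # drop a secondary identifier column (e.g. Entrez_Gene_Id) if present
        if str(df.columns[0]).strip().lower() in {"entrez_gene_id", "entrez_id"}:
            df = df.drop(columns=df.columns[0])
        mat = df.T
    elif orientation == "samples_by_genes":
        mat = df.set_index(df.columns[0])
    else:
        raise DataFormatError(f"unknown expression orientation {orientation!r}")
    mat.index = mat.index.astype(str)
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric expression values") from exc
    return mat


def _map_status(values: pd.Series, status_map: Mapping[str, int], path) -> np.ndarray:
    lut = {str(k).strip().upper(): int(v) for k, v in status_map.items()}
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        key = str(v).strip().upper()
        if key not in lut:
            raise DataFormatError(f"{path}: unmapped status value {v!r}")
        out[i] = lut[key]
    return out


def load_cancer_dataset(
    expression_table,
    clinical_table,
    cancer_id: str,
    *,
    orientation: str = "auto",
    sample_col: str = "SAMPLE_ID",
    time_col: str = "OS_MONTHS",
    status_col: str = "OS_STATUS",
    status_map: Mapping[str, int] | None = None,
) -> CancerDataset:
    """Load one cohort from tab-separated expression and clinical tables.

    Samples are restricted to those present in both tables.  Times stay in
    raw months until :func:`canonicalize`.

    Raises
    ------
    DataFormatError
        Missing required columns or non-numeric values.
    EmptyJoinError
        No sample appears in both tables.
    NonPositiveTimeError
        A matched sample has a nonpositive survival time.
    """
    status_map = dict(status_map or DEFAULT_STATUS_MAP)
    expr = _read_expression(expression_table, orientation)

    clin = pd.read_csv(clinical_table, sep="\t", dtype={sample_col: str})
    for col in (sample_col, time_col, status_col):
        if col not in clin.columns:
            raise DataFormatError(
                f"{clinical_table}: missing required column {col!r}"
            )
    clin = clin.set_index(clin[sample_col].astype(str))

    shared = [s for s in expr.index if s in clin.index]
    if not shared:
        raise EmptyJoinError(
            f"{cancer_id}: no samples shared between expression and clinical tables"
        )
    expr = expr.loc[shared]
    clin = clin.loc[shared]

    times = pd.to_numeric(clin[time_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(times).any():
        bad = np.asarray(shared)[np.isnan(times)][0]
        raise DataFormatError(f"{cancer_id}: non-numeric survival time for {bad!r}")
    nonpos = times <= 0
    if nonpos.any():
        bad = np.asarray(shared)[nonpos][0]
        raise NonPositiveTimeError(
            f"{cancer_id}: nonpositive survival time for sample {bad!r}"
        )
    delta = _map_status(clin[status_col], status_map, clinical_table)

    return CancerDataset(
        cancer_id=cancer_id,
        gene_ids=[str(g) for g in expr.columns],
        X=expr.to_numpy(dtype=float),
        y=times,
        delta=delta,
    )


def load_panel(path) -> list:
    """Read a gene panel: plain text, one symbol per line, '#' comments."""
    panel = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                panel.append(sym)
    return panel


# ---------------------------------------------------------------------------
# Canonicalization / alignment
# ---------------------------------------------------------------------------


def canonicalize(dataset: CancerDataset) -> CancerDataset:
    """Log-transform times and sort ascending, events before censorings at ties.

    Idempotent: canonical inputs are returned unchanged (a copy).
    """
    if dataset.canonical:
        return replace(dataset)
    if np.any(dataset.y <= 0):
        i = int(np.argmax(dataset.y <= 0))
        raise NonPositiveTimeError(
            f"{dataset.cancer_id}: nonpositive time at row {i} "
            f"(t={dataset.y[i]!r})"
        )
    logy = np.log(dataset.y)
    order = np.lexsort((-dataset.delta, logy))
    return CancerDataset(
        cancer_id=dataset.cancer_id,
        gene_ids=list(dataset.gene_ids),
        X=dataset.X[order],
        y=logy[order],
        delta=dataset.delta[order],
        canonical=True,
    )


def align_genes(
    datasets: Sequence[CancerDataset], panel: Sequence[str] | None = None
) -> MultiCancerData:
    """Restrict all cohorts to their shared genes (and panel), sorted.

    Gene order in the output is lexicographic for determinism.
    """
    if len(datasets) < 2:
        raise DataFormatError("align_genes needs at least two datasets")
    shared = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        shared &= set(ds.gene_ids)
    if panel is not None:
        shared &= set(panel)
    if not shared:
        raise EmptyIntersectionError("no genes shared across cohorts (and panel)")
    genes = sorted(shared)
    aligned = []
    for ds in datasets:
        pos = {g: i for i, g in enumerate(ds.gene_ids)}
        cols = [pos[g] for g in genes]
        aligned.append(
            CancerDataset(
                cancer_id=ds.cancer_id,
                gene_ids=genes,
                X=ds.X[:, cols],
                y=ds.y,
                delta=ds.delta,
                canonical=ds.canonical,
            )
        )
    return MultiCancerData(aligned)


# ---------------------------------------------------------------------------
# Weighted standardization
# ---------------------------------------------------------------------------


def weighted_standardize(dataset: CancerDataset, weights):
    """Center y and X by KM-weighted means; scale X columns to unit weighted
    mean square.

    The scale uses ``sqrt(mean_i w_i * (x_i - xbar)^2)`` with the plain 1/n
    mean, so that after standardization ``(1/n) sum_i w_i x_i^2 = 1`` — the
    curvature of each coordinate-descent subproblem is then exactly 1.
    Columns with zero weighted variance are flagged degenerate (zeroed out,
    ``retained=False``) and must be skipped by the solvers.

    Returns ``(standardized_dataset, record)``.
    """
    dataset.require_canonical()
    w = np.asarray(weights.w if hasattr(weights, "w") else weights, dtype=float)
    if w.shape != (dataset.n,):
        raise DataFormatError("weights not aligned to dataset rows")
    wsum = w.sum()
    if wsum <= 0:
        raise DegenerateWeightsError(
            f"{dataset.cancer_id}: all KM weights are zero"
        )
    n = dataset.n
    y_mean = float(w @ dataset.y / wsum)
    x_mean = (w @ dataset.X) / wsum
    Xc = dataset.X - x_mean
    msq = (w @ (Xc**2)) / n
    scale = np.sqrt(msq)
    retained = scale > 0
    scale_out = np.where(retained, scale, np.nan)
    Xs = np.zeros_like(Xc)
    Xs[:, retained] = Xc[:, retained] / scale[retained]
    std = CancerDataset(
        cancer_id=dataset.cancer_id,
        gene_ids=list(dataset.gene_ids),
        X=Xs,
        y=dataset.y - y_mean,
        delta=dataset.delta,
        canonical=True,
    )
    rec = StandardizationRecord(
        y_mean=y_mean, x_mean=x_mean, x_scale=scale_out, retained=retained
    )
    return std, rec
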