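"""Kaplan-Meier (Stute) jump weights for the weighted least-squares AFT loss.

For a cohort sorted ascending by observed time (events before censorings at
ties), the weight of row i is

    w_1 = delta_1 / n
    w_i = delta_i / (n - i + 1) * prod_{l=1}^{i-1} ((n - l) / (n - l + 1))^delta_l

These are exactly the jumps of the Kaplan-Meier estimator of the time
distribution; censored rows carry weight zero, and the weights sum to one iff
the largest observation is an event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import CancerDataset
from .exceptions import NotCanonicalError

__all__ = ["KMWeights", "compute_km_weights"]


@dataclass
class KMWeights:
    """Nonnegative loss weights aligned to a canonicalized cohort."""

    w: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.w.sum())


def _check_sorted(dataset: CancerDataset) -> None:
    y, d = dataset.y, dataset.delta
    if np.any(np.diff(y) < 0):
        raise NotCanonicalError("dataset rows are not sorted ascending by y")
    # at ties, events must precede censorings
    ties = np.flatnonzero(np.diff(y) == 0)
    if np.any(d[ties] < d[ties + 1]):
        raise NotCanonicalError("tied rows must have events before censorings")


def compute_km_weights(dataset: CancerDataset, renormalize: bool = False) -> KMWeights:
    """Stute weights of a canonicalized cohort.

    Parameters
    ----------
    dataset : CancerDataset
        Must be canonical (sorted); a precondition error is raised otherwise.
    renormalize : bool
        If True and the largest observation is censored (so the raw jumps sum
        to < 1), rescale the weights to sum to one.  Off by default: the raw
        KM jumps are used as-is.
    """
    dataset.require_canonical()
    _check_sorted(dataset)
    n = dataset.n
    d = dataset.delta.astype(float)
    i = np.arange(1, n + 1, dtype=float)
    # survival factor prod_{l<i} ((n-l)/(n-l+1))^delta_l, computed by cumprod
    factors = np.ones(n)
    if n > 1:
        l = np.arange(1, n, dtype=float)
        step = ((n - l) / (n - l + 1)) ** d[:-1]
        factors[1:] = np.cumprod(step)
    w = d / (n - i + 1) * factors
    if renormalize:
        total = w.sum()
        if total > 0:
            w = w / total
    return KMWeights(w=w)
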