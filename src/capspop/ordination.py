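"""Principal coordinates analysis (classical MDS) of a distance matrix."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from capspop.distance_clustering import DistanceMatrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9


@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray  # accessions x retained axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, sums to 100 over positives
    negative_eigenvalues: np.ndarray  # diagnostics only

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.coordinates,
            index=self.labels,
            columns=[f"axis_{i+1}" for i in range(self.coordinates.shape[1])],
        )


def pcoa(dm: DistanceMatrix, n_axes: int | None = None, cailliez: bool = False) -> PCoAResult:
    """Gower-centered eigendecomposition of -1/2 d^2.

    Coordinates are eigenvector * sqrt(eigenvalue) for positive eigenvalues;
    negative eigenvalues are reported but their axes dropped (optionally
    apply the Cailliez additive correction first).  Percent variance is
    taken over the positive-eigenvalue total.  Axis signs are fixed by
    making each axis's largest-magnitude loading positive.
    """
    d = np.asarray(dm.d, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix must be finite")
    n = d.shape[0]
    if cailliez:
        d = d + _cailliez_constant(d) * (1 - np.eye(n))
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > _EIG_TOL * max(1.0, abs(eigvals).max(initial=1.0))
    pos_vals = eigvals[positive]
    neg_vals = eigvals[eigvals < -_EIG_TOL * max(1.0, abs(eigvals).max(initial=1.0))]
    if neg_vals.size:
        logger.info("pcoa: %d negative eigenvalues (min %.3g)", neg_vals.size, neg_vals.min())
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    # sign convention: largest-magnitude loading positive on every axis
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    total = pos_vals.sum()
    percent = 100.0 * pos_vals / total if total > 0 else np.zeros_like(pos_vals)
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            logger.warning(
                "pcoa: requested %d axes, only %d positive eigenvalues", n_axes, coords.shape[1]
            )
            n_axes = coords.shape[1]
        coords = coords[:, :n_axes]
        pos_vals = pos_vals[:n_axes]
        percent = percent[:n_axes]
    return PCoAResult(
        labels=list(dm.labels),
        coordinates=coords,
        eigenvalues=pos_vals,
        percent_variance=percent,
        negative_eigenvalues=neg_vals,
    )


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making the configuration Euclidean."""
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    delta1 = centering @ (-0.5 * d**2) @ centering
    delta2 = centering @ (-0.5 * d) @ centering
    upper = np.block([[np.zeros((n, n)), 2 * delta1], [-np.eye(n), -4 * delta2]])
    eigs = np.linalg.eigvals(upper)
    c = max(eigs.real.max(), 0.0)
    return c
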