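"""Principal coordinates analysis (metric MDS) of a distance matrix.

Classical Gower PCoA: double-centre ``-0.5 * d^2``, eigendecompose, and
scale eigenvectors by the square roots of their (positive) eigenvalues.
Negative eigenvalues, which arise when the distances are not Euclidean-
embeddable (common for generalized Euclidean distances with imputation),
are reported in the eigenvalue spectrum but never yield score axes; no
Cailliez/Lingoes correction is applied by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from morphorates.distances import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class Ordination:
    """Taxon scores on ranked PCo axes plus the full eigenvalue spectrum."""

    labels: list[str]
    scores: np.ndarray  # taxa x retained axes
    eigenvalues: np.ndarray  # full spectrum, descending (may be negative)
    n_retained: int

    def scores_for(self, labels: "list[str]", axes: "slice | list[int] | None" = None):
        idx = [self.labels.index(l) for l in labels]
        s = self.scores[idx]
        return s if axes is None else s[:, axes]

    def to_csv(self, scores_path: "str | Path", eigenvalues_path: "str | Path | None" = None):
        cols = [f"PCo{i + 1}" for i in range(self.scores.shape[1])]
        pd.DataFrame(self.scores, index=self.labels, columns=cols).to_csv(scores_path)
        if eigenvalues_path is not None:
            pd.DataFrame({"eigenvalue": self.eigenvalues}).to_csv(
                eigenvalues_path, index_label="axis"
            )


def pcoa(d: DistanceMatrix, n_axes: int = 20, correction: str = "none") -> Ordination:
    """Principal coordinates of a distance matrix.

    Parameters
    ----------
    d
        Symmetric distances with zero diagonal.
    n_axes
        Number of axes requested (default 20).  If fewer positive
        eigenvalues exist, the returned axes are truncated with a warning.
    correction
        ``"none"`` (default), ``"lingoes"`` (add -2*min eigenvalue to all
        squared distances) or ``"cailliez"`` (additive constant on the
        distances themselves).
    """
    n = d.n
    if n_axes > n - 1:
        raise ValueError(f"n_axes ({n_axes}) must be <= taxa - 1 ({n - 1})")
    dm = d.d
    if correction == "cailliez":
        dm = dm + _cailliez_constant(dm) * (1 - np.eye(n))
    sq = dm ** 2
    if correction == "lingoes":
        evals = _centred_eigenvalues(sq)
        if evals.min() < 0:
            sq = sq + 2.0 * (-evals.min()) * (1 - np.eye(n))
    elif correction not in ("none", "cailliez"):
        raise ValueError(f"unknown correction {correction!r}")
    b = _double_centre(sq)
    evals, evecs = scipy.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # round eigenvalues that are numerically zero
    evals = np.where(np.abs(evals) < 1e-10 * max(1.0, np.abs(evals).max()), 0.0, evals)
    n_pos = int(np.sum(evals > 0))
    if evals.min() < 0:
        logger.info(
            "PCoA: %d negative eigenvalues (most negative %.4g; largest %.4g)",
            int(np.sum(evals < 0)), evals.min(), evals.max(),
        )
    k = min(n_axes, n_pos)
    if k < n_axes:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k} axes "
            f"instead of the requested {n_axes}",
            stacklevel=2,
        )
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    return Ordination(labels=list(d.labels), scores=scores, eigenvalues=evals,
                      n_retained=k)


def _double_centre(sq: np.ndarray) -> np.ndarray:
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ sq @ j


def _centred_eigenvalues(sq: np.ndarray) -> np.ndarray:
    return scipy.linalg.eigvalsh(_double_centre(sq))


def _cailliez_constant(dm: np.ndarray) -> float:
    """Smallest constant c such that d + c is Euclidean-embeddable."""
    n = dm.shape[0]
    delta1 = _double_centre(dm ** 2)
    delta2 = _double_centre(dm)
    zero = np.zeros((n, n))
    eye = np.eye(n)
    block = np.block([[zero, 2.0 * delta1], [-eye, -4.0 * delta2]])
    evals = np.linalg.eigvals(block)
    return max(float(np.max(evals.real)), 0.0)
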