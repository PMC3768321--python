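"""Inter-taxon distances: generalized Euclidean (morphological) and patristic.

The generalized Euclidean distance (GED) extends the ordinary Euclidean
distance between character-state row vectors to matrices with missing data:
for each pair of taxa, characters that cannot be compared (one or both
cells missing) contribute the pair's mean squared single-character
difference over the characters that *can* be compared.  With complete data
the GED reduces exactly to the Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from morphorates.io_core import CharacterMatrix, DatedTree


class IncomparablePairError(ValueError):
    """Two taxa share no jointly scored character."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-character counts."""

    labels: list[str]
    d: np.ndarray
    comparable_counts: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector (scipy 'condensed' order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def subset(self, labels: "list[str]") -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        cc = None
        if self.comparable_counts is not None:
            cc = self.comparable_counts[np.ix_(idx, idx)]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], cc)

    def drop(self, labels: "set[str] | list[str]") -> "DistanceMatrix":
        keep = [l for l in self.labels if l not in set(labels)]
        return self.subset(keep)

    def to_csv(self, path: "str | Path") -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path)

    def to_phylip(self, path: "str | Path") -> None:
        """PHYLIP-style lower-triangle text."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, label in enumerate(self.labels):
                row = " ".join(f"{self.d[i, j]:.6f}" for j in range(i))
                fh.write(f"{label.replace(' ', '_')} {row}".rstrip() + "\n")


def _pair_sq_diffs(
    row_a, row_b, ordering: "list[str]", polymorphism: str
) -> "tuple[np.ndarray, np.ndarray]":
    """Squared per-character differences and comparability mask for one pair."""
    n = len(row_a)
    sq = np.zeros(n)
    comparable = np.zeros(n, dtype=bool)
    for j in range(n):
        a, b = row_a[j], row_b[j]
        if a is None or b is None:
            continue
        comparable[j] = True
        if ordering[j] == "ordered":
            diffs = [abs(x - y) for x in a for y in b]
        else:
            diffs = [0.0 if x == y else 1.0 for x in a for y in b]
        delta = min(diffs) if polymorphism == "min" else float(np.mean(diffs))
        sq[j] = delta * delta
    return sq, comparable


def ged_matrix(m: CharacterMatrix, polymorphism: str = "min") -> DistanceMatrix:
    """Pairwise generalized Euclidean distances from a character matrix.

    Per character, the single-character difference is ``|x - y|`` for
    ordered characters and 0/1 for unordered ones; polymorphic cells score
    the minimum difference over member states (``polymorphism="mean"``
    averages instead).  For a pair's non-comparable characters the squared
    difference is imputed as the weighted mean squared difference over the
    pair's comparable characters; the distance is
    ``sqrt(sum_i w_i * delta_i^2)`` over all characters.

    Raises
    ------
    IncomparablePairError
        If some pair of taxa shares no jointly scored character.
    """
    if m.n_taxa < 2:
        raise ValueError("need at least two taxa")
    if polymorphism not in ("min", "mean"):
        raise ValueError("polymorphism must be 'min' or 'mean'")
    n = m.n_taxa
    w = m.weights
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    bad_pairs = []
    for i in range(n):
        counts[i, i] = int(np.sum(m.scored_mask()[i])) if n else 0
        for k in range(i + 1, n):
            sq, comp = _pair_sq_diffs(m.cells[i], m.cells[k], m.ordering, polymorphism)
            counts[i, k] = counts[k, i] = int(comp.sum())
            w_comp = w[comp]
            if w_comp.sum() <= 0:
                bad_pairs.append((m.taxon_labels[i], m.taxon_labels[k]))
                continue
            mean_sq = float(np.dot(w_comp, sq[comp]) / w_comp.sum())
            sq_full = sq.copy()
            sq_full[~comp] = mean_sq
            d[i, k] = d[k, i] = float(np.sqrt(np.dot(w, sq_full)))
    if bad_pairs:
        raise IncomparablePairError(
            f"pairs with no jointly scored characters: {bad_pairs}"
        )
    return DistanceMatrix(list(m.taxon_labels), d, counts)


def patristic_distances(t: DatedTree, transform: str = "none") -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between tips, in Myr.

    ``transform="sqrt"`` returns elementwise square roots, the variance-
    stabilizing scale commonly used when correlating phylogenetic with
    morphological distances.
    """
    if transform not in ("none", "sqrt"):
        raise ValueError("transform must be 'none' or 'sqrt'")
    if t.tree.seed_node is None:
        raise ValueError("tree must be rooted")
    for e in t.branches():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch duration")
    pdm = t.tree.phylogenetic_distance_matrix()
    labels = t.tip_labels
    taxa = {taxon.label: taxon for taxon in t.tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    if transform == "sqrt":
        d = np.sqrt(d)
    return DistanceMatrix(labels, d)
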