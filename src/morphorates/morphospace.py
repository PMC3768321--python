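"""Phylomorphospace node placement and 3-D spatial clustering statistics.

Internal-node positions in morphospace are the Brownian-motion maximum-
likelihood ancestral estimates on the dated tree, computed axis by axis.
Spatial structure of the taxon cloud in the first three ordination axes is
quantified with Ripley's K function inside an axis-aligned observation
box, compared against a Monte Carlo envelope built from uniform (CSR —
complete spatial randomness) point patterns of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from morphorates.io_core import DatedTree
from morphorates.ordination import Ordination


# ---------------------------------------------------------------------------
# Ancestral coordinates (Brownian-motion ML)
# ---------------------------------------------------------------------------


def ancestral_coordinates(
    t: DatedTree,
    o: Ordination,
    axes: "list[int] | None" = None,
    epsilon: float = 1e-8,
) -> pd.DataFrame:
    """Brownian-motion ML estimates of internal-node positions.

    For Brownian motion the ML ancestral states jointly minimize
    ``sum((x_parent - x_child)^2 / duration)``; the solution satisfies, at
    every internal node, a weighted average over its neighbours with
    weights 1/duration (equivalently a GLS fit).  The linear system is
    solved exactly.  Tips keep their observed scores.

    Zero-duration branches get ``epsilon`` added (with a warning) so the
    weights stay finite.

    Returns a DataFrame indexed by node label (tips by taxon label,
    internal nodes ``node<k>`` in preorder) with one column per axis.
    """
    tips = set(t.tip_labels)
    if not tips.issubset(set(o.labels)):
        raise ValueError("tree tips must be a subset of ordination labels")
    if axes is None:
        axes = list(range(o.scores.shape[1]))

    nodes = list(t.tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaf_rows = {n: o.labels.index(n.taxon.label) for n in nodes if n.is_leaf()}

    durations = {}
    warned = False
    for node in nodes[1:]:
        dur = node.edge.length or 0.0
        if dur <= 0:
            if not warned:
                warnings.warn(
                    f"zero-duration branches; adding epsilon={epsilon}",
                    stacklevel=2,
                )
                warned = True
            dur = epsilon
        durations[node] = dur

    m = len(internal)
    int_index = {n: i for i, n in enumerate(internal)}
    a = np.zeros((m, m))
    b = np.zeros((m, len(axes)))
    x_tips = o.scores[:, axes]
    for node in internal:
        i = int_index[node]
        neighbours = list(node.child_nodes())
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
        for nb in neighbours:
            w = 1.0 / durations[nb if nb is not node.parent_node else node]
            a[i, i] += w
            if nb.is_leaf():
                b[i] += w * x_tips[leaf_rows[nb]]
            else:
                a[i, int_index[nb]] -= w
    anc = np.linalg.solve(a, b)

    labels, coords = [], []
    k = 0
    for node in nodes:
        if node.is_leaf():
            labels.append(node.taxon.label)
            coords.append(x_tips[leaf_rows[node]])
        else:
            k += 1
            labels.append(node.label or f"node{k}")
            coords.append(anc[int_index[node]])
    return pd.DataFrame(
        np.asarray(coords), index=labels, columns=[f"axis{ax + 1}" for ax in axes]
    )


# ---------------------------------------------------------------------------
# Ripley's K in three dimensions
# ---------------------------------------------------------------------------


@dataclass
class Box3D:
    """Axis-aligned 3-D observation window."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != (3,) or self.hi.shape != (3,):
            raise ValueError("box bounds must be 3-vectors")
        if np.any(self.hi - self.lo <= 0):
            raise ValueError("degenerate box: zero extent on some axis")

    @property
    def edges(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))

    @classmethod
    def bounding(cls, points: np.ndarray, pad_fraction: float = 0.05) -> "Box3D":
        """Bounding box of the points, expanded by a fraction per side."""
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        return cls(lo - pad_fraction * span, hi + pad_fraction * span)

    def contains(self, points: np.ndarray) -> bool:
        return bool(
            np.all(points >= self.lo - 1e-12) and np.all(points <= self.hi + 1e-12)
        )


@dataclass
class KFunctionResult:
    """Ripley's K estimate with CSR reference and Monte Carlo envelope."""

    r_grid: np.ndarray
    k_obs: np.ndarray
    k_theo: np.ndarray
    envelope_lo: "np.ndarray | None"
    envelope_hi: "np.ndarray | None"
    n_points: int
    box: Box3D

    def clustered_at(self) -> np.ndarray:
        """Boolean mask of r values where K exceeds the upper envelope."""
        if self.envelope_hi is None:
            raise ValueError("no envelope computed")
        return self.k_obs > self.envelope_hi

    def to_frame(self) -> pd.DataFrame:
        data = {"r": self.r_grid, "k_obs": self.k_obs, "k_theo": self.k_theo}
        if self.envelope_lo is not None:
            data["envelope_lo"] = self.envelope_lo
            data["envelope_hi"] = self.envelope_hi
        return pd.DataFrame(data)


def default_r_grid(box: Box3D, n_r: int = 100) -> np.ndarray:
    """0 to half the shortest box edge."""
    return np.linspace(0.0, float(box.edges.min()) / 2.0, n_r)


def ripley_k_3d(
    points: np.ndarray,
    r_grid: "np.ndarray | None" = None,
    box: "Box3D | None" = None,
    correction: str = "translation",
) -> KFunctionResult:
    """Ripley's K function of a 3-D point pattern.

    ``K(r) = V / (n (n-1)) * sum_{i != j} e_ij 1{d_ij <= r}`` with V the
    box volume and ``e_ij`` the translation edge-correction weight
    ``V / prod_k (L_k - |dx_k|)`` (1 when ``correction="none"``).  Under
    CSR the expectation is ``4/3 pi r^3``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be n x 3")
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if correction not in ("none", "translation"):
        raise ValueError(f"unknown correction {correction!r}")
    if box is None:
        box = Box3D.bounding(points)
    if not box.contains(points):
        raise ValueError("box does not enclose all points")
    if r_grid is None:
        r_grid = default_r_grid(box)
    r_grid = np.asarray(r_grid, dtype=float)

    diff = points[:, None, :] - points[None, :, :]  # n x n x 3
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    if correction == "translation":
        shifted = box.edges[None, None, :] - np.abs(diff)
        with np.errstate(divide="ignore"):
            weights = box.volume / np.prod(shifted, axis=-1)
    else:
        weights = np.ones((n, n))
    np.fill_diagonal(weights, 0.0)
    np.fill_diagonal(dist, np.inf)

    indicator = dist[:, :, None] <= r_grid[None, None, :]
    k_obs = (weights[:, :, None] * indicator).sum(axis=(0, 1))
    k_obs *= box.volume / (n * (n - 1))
    k_theo = 4.0 / 3.0 * np.pi * r_grid ** 3
    return KFunctionResult(
        r_grid=r_grid,
        k_obs=k_obs,
        k_theo=k_theo,
        envelope_lo=None,
        envelope_hi=None,
        n_points=n,
        box=box,
    )


def csr_envelope(
    n: int,
    box: Box3D,
    r_grid: np.ndarray,
    nsim: int = 999,
    seed: "int | np.random.Generator" = 0,
    correction: str = "translation",
) -> "tuple[np.ndarray, np.ndarray]":
    """Pointwise rank-1 (min/max) envelope of K under CSR.

    Simulates ``nsim`` uniform n-point patterns in the box and returns the
    pointwise minimum and maximum of their K estimates.  With nsim = 999
    a one-sided pointwise exceedance has nominal probability 1/1000.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    lo = np.full(len(r_grid), np.inf)
    hi = np.full(len(r_grid), -np.inf)
    for _ in range(nsim):
        pts = rng.uniform(box.lo, box.hi, size=(n, 3))
        k = ripley_k_3d(pts, r_grid=r_grid, box=box, correction=correction).k_obs
        lo = np.minimum(lo, k)
        hi = np.maximum(hi, k)
    return lo, hi


def k_with_envelope(
    points: np.ndarray,
    nsim: int = 999,
    seed: "int | np.random.Generator" = 0,
    r_grid: "np.ndarray | None" = None,
    box: "Box3D | None" = None,
    correction: str = "translation",
) -> KFunctionResult:
    """Observed K plus a CSR Monte Carlo envelope in one call."""
    result = ripley_k_3d(points, r_grid=r_grid, box=box, correction=correction)
    lo, hi = csr_envelope(
        result.n_points, result.box, result.r_grid, nsim=nsim, seed=seed,
        correction=correction,
    )
    result.envelope_lo = lo
    result.envelope_hi = hi
    return result


# ---------------------------------------------------------------------------
# Diagnostic plots
# ---------------------------------------------------------------------------


def plot_k_function(result: KFunctionResult, path=None):
    """Diagnostic plot of K(r) against the CSR expectation and envelope."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if result.envelope_lo is not None:
        ax.fill_between(
            result.r_grid, result.envelope_lo, result.envelope_hi,
            color="0.8", label="CSR envelope",
        )
    ax.plot(result.r_grid, result.k_theo, "--", color="0.3", label="CSR expectation")
    ax.plot(result.r_grid, result.k_obs, color="C0", label="observed K")
    ax.set_xlabel("r (dimensionless)")
    ax.set_ylabel("K(r)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_phylomorphospace(t: DatedTree, o: Ordination, axes=(0, 1), path=None):
    """Ordination scatter with tree branches drawn between node positions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ancestral_coordinates(t, o, axes=list(axes))
    names = {}
    k = 0
    for node in t.tree.preorder_node_iter():
        if node.is_leaf():
            names[node] = node.taxon.label
        else:
            k += 1
            names[node] = node.label or f"node{k}"
    fig, ax = plt.subplots(figsize=(5, 5))
    for node in t.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a = coords.loc[names[node.parent_node]]
        b = coords.loc[names[node]]
        ax.plot([a.iloc[0], b.iloc[0]], [a.iloc[1], b.iloc[1]],
                color="0.6", lw=0.7, zorder=1)
    tips = coords.loc[[l for l in t.tip_labels]]
    ax.scatter(tips.iloc[:, 0], tips.iloc[:, 1], s=18, zorder=2)
    ax.set_xlabel(f"PCo{axes[0] + 1}")
    ax.set_ylabel(f"PCo{axes[1] + 1}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
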