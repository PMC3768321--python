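"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a fossil-clade study dataset: a birth-death tree
whose extinct tips are retained (so taxa terminate throughout the tree's
history, as in the fossil record), discrete characters evolved under an
equal-rates Mk model with optional per-clade rate multipliers, per-taxon
missing-data masking, preservation-thinned stratigraphic ranges around
each tip, and a three-group labelling (a basal paraphyletic array plus
two derived clades) read off the simulated topology.

Defaults correspond to the study conditions the pipeline is designed
for: 54 taxa, 150 characters with 2-5 states (mostly binary), a Late
Permian - Early Jurassic time window (youngest tips near 183 Ma), and
enough character change for parsimony reconstruction to be informative
(a few changes per character over the whole tree).

All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from morphorates.io_core import CharacterMatrix, DatedTree, StratRange


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset."""

    n_taxa: int = 54
    n_characters: int = 150
    #: sampling probabilities of per-character state counts 2..5
    state_count_probs: tuple = (0.55, 0.25, 0.12, 0.08)
    birth_rate: float = 0.09  # per lineage per Myr
    death_rate: float = 0.045
    #: expected changes per character per Myr (rate of leaving the state)
    char_rate: float = 0.005
    #: clade label -> rate multiplier for branches inside that clade
    clade_rate_multipliers: dict = field(default_factory=dict)
    #: (lo, hi) of the per-taxon uniform missingness fraction
    missingness_range: tuple = (0.05, 0.55)
    #: rate (1/Myr) of the exponential FAD lag toward older ages
    preservation_rate: float = 0.5
    #: mean (Myr) of the exponential observed range duration
    range_duration_mean: float = 3.0
    #: age (Ma) assigned to the youngest tip, anchoring the absolute scale
    youngest_tip_age: float = 183.0
    resample_invariant: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missingness_range[0] <= self.missingness_range[1] < 1:
            raise ValueError("missingness fractions must lie in [0, 1)")
        for rate in (self.birth_rate, self.death_rate, self.char_rate,
                     self.preservation_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def simulate_dated_tree(cfg: SimulationConfig, seed=None) -> DatedTree:
    """Birth-death tree conditioned on total (extant + extinct) tip count.

    Extinct tips are retained, so tip ages are spread through the tree's
    history.  Node ages are absolute Ma: the youngest tip sits at
    ``cfg.youngest_tip_age``.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    if cfg.n_taxa < 2:
        raise ValueError("need at least two taxa")
    import random as _random

    pyrng = _random.Random(int(rng.integers(0, 2 ** 31)))
    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=cfg.death_rate,
        num_total_tips=cfg.n_taxa,
        is_retain_extinct_tips=True,
        rng=pyrng,
        repeat_until_success=True,
    )
    # strip the simulator's extinct/extant label decorations; relabel tips
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        label = f"T{i:03d}"
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label)
        leaf.taxon.label = label
    tree.purge_taxon_namespace()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length or 0) <= 0:
            edge.length = 1e-6
    tree.seed_node.edge.length = None
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    max_depth = max(depths[l] for l in tree.leaf_node_iter())
    root_age = max_depth + cfg.youngest_tip_age
    return DatedTree(tree=tree, root_age=float(root_age))


def assign_groups(t: DatedTree, n_min_fraction: float = 1 / 6) -> dict[str, str]:
    """Label tips as two derived clades plus a basal residue.

    The largest proper clade holding between ``n_min_fraction`` and half
    of the tips becomes ``cladeA``; the largest clade disjoint from it in
    the same size window becomes ``cladeB``; all remaining tips are
    ``basal``.  Deterministic for a given topology.
    """
    tips = t.tip_labels
    n = len(tips)
    lo, hi = max(2, int(np.ceil(n_min_fraction * n))), n // 2
    min_basal = max(3, int(np.ceil(0.1 * n)))
    clades = []
    for node in t.tree.preorder_internal_node_iter():
        if node is t.tree.seed_node:
            continue
        members = [l.taxon.label for l in node.leaf_iter()]
        if lo <= len(members) <= hi:
            clades.append(set(members))
    clades.sort(key=len, reverse=True)
    group_a: set = set()
    group_b: set = set()
    for a in clades:
        b = next(
            (c for c in clades if not (c & a) and n - len(a) - len(c) >= min_basal),
            None,
        )
        if b is not None:
            group_a, group_b = a, b
            break
    if not group_a:  # degenerate small tree: split the tip list
        third = max(1, n // 3)
        group_a, group_b = set(tips[:third]), set(tips[third : 2 * third])
    labels = {}
    for tip in tips:
        if tip in group_a:
            labels[tip] = "cladeA"
        elif tip in group_b:
            labels[tip] = "cladeB"
        else:
            labels[tip] = "basal"
    return labels


# ---------------------------------------------------------------------------
# Characters
# ---------------------------------------------------------------------------


def _branch_rate_multipliers(
    t: DatedTree, cfg: SimulationConfig, groups: "dict[str, str] | None"
) -> dict[int, float]:
    """Per-branch multiplier: branches inside a named clade (stem included)."""
    mult = {id(e.head_node): 1.0 for e in t.branches()}
    if not cfg.clade_rate_multipliers:
        return mult
    if groups is None:
        groups = assign_groups(t)
    for clade, factor in cfg.clade_rate_multipliers.items():
        members = {tip for tip, g in groups.items() if g == clade}
        if not members:
            continue
        mrca = t.tree.mrca(taxon_labels=list(members))
        # clade = mrca subtree; the stem branch is mrca's own edge
        for node in mrca.preorder_iter():
            if id(node) in mult:
                mult[id(node)] = factor
    return mult


def simulate_characters(
    t: DatedTree,
    cfg: SimulationConfig,
    seed=None,
    groups: "dict[str, str] | None" = None,
) -> CharacterMatrix:
    """Evolve discrete characters under an equal-rates Mk process.

    Each character draws its state count from ``cfg.state_count_probs``
    (2-5 states) and evolves with total leaving rate ``cfg.char_rate``
    (uniform among the other states), scaled per branch by any clade
    multiplier.  Root states are uniform.  With
    ``cfg.resample_invariant`` characters invariant across tips are
    redrawn (up to a bounded number of attempts), mimicking matrices
    built from variable characters only.
    """
    rng = _rng(cfg.seed + 1 if seed is None else seed)
    n_chars = cfg.n_characters
    k_states = rng.choice([2, 3, 4, 5], size=n_chars, p=cfg.state_count_probs)
    mult = _branch_rate_multipliers(t, cfg, groups)

    def evolve() -> dict[str, np.ndarray]:
        states: dict[int, np.ndarray] = {}
        root = t.tree.seed_node
        states[id(root)] = (rng.random(n_chars) * k_states).astype(int)
        tip_states: dict[str, np.ndarray] = {}
        for node in t.tree.preorder_node_iter():
            if node is root:
                current = states[id(root)]
            else:
                dur = node.edge.length or 0.0
                rate = cfg.char_rate * mult[id(node)]
                parent = states[id(node.parent_node)]
                # Mk transition: P(stay) = 1/k + (1-1/k) exp(-k*r*t/(k-1))
                p_stay = 1.0 / k_states + (1 - 1.0 / k_states) * np.exp(
                    -k_states * rate * dur / (k_states - 1)
                )
                stay = rng.random(n_chars) < p_stay
                shift = 1 + (rng.random(n_chars) * (k_states - 1)).astype(int)
                current = np.where(stay, parent, (parent + shift) % k_states)
                states[id(node)] = current
            if node.is_leaf():
                tip_states[node.taxon.label] = current.copy()
        return tip_states

    tips = evolve()
    labels = t.tip_labels
    data = np.stack([tips[l] for l in labels])  # taxa x chars

    if cfg.resample_invariant:
        for _ in range(200):
            invariant = np.all(data == data[0], axis=0)
            if not invariant.any():
                break
            redraw = evolve()
            redraw_data = np.stack([redraw[l] for l in labels])
            data[:, invariant] = redraw_data[:, invariant]

    cells = [[frozenset([int(s)]) for s in row] for row in data]
    return CharacterMatrix(taxon_labels=list(labels), cells=cells)


def apply_missingness(m: CharacterMatrix, cfg: SimulationConfig, seed=None) -> CharacterMatrix:
    """Mask cells independently at a per-taxon missingness fraction."""
    rng = _rng(cfg.seed + 2 if seed is None else seed)
    lo, hi = cfg.missingness_range
    fractions = rng.uniform(lo, hi, size=m.n_taxa)
    cells = []
    for i, row in enumerate(m.cells):
        mask = rng.random(m.n_characters) < fractions[i]
        cells.append([None if mask[j] else cell for j, cell in enumerate(row)])
    return CharacterMatrix(
        taxon_labels=list(m.taxon_labels),
        cells=cells,
        ordering=list(m.ordering),
        weights=m.weights.copy(),
    )


# ---------------------------------------------------------------------------
# Stratigraphic ranges
# ---------------------------------------------------------------------------


def simulate_ranges(t: DatedTree, cfg: SimulationConfig, seed=None) -> list[StratRange]:
    """Preservation-thinned observed ranges around each tip.

    FAD = tip age plus an exponential lag toward older ages (rate
    ``cfg.preservation_rate``), truncated at the subtending branch's
    origin; LAD = FAD minus an exponential duration (mean
    ``cfg.range_duration_mean``), truncated no younger than slightly
    below the tip age.
    """
    rng = _rng(cfg.seed + 3 if seed is None else seed)
    ages = t.node_ages()
    ranges = []
    for leaf in t.tree.leaf_node_iter():
        tip_age = ages[leaf]
        parent_age = ages[leaf.parent_node] if leaf.parent_node else tip_age
        if cfg.preservation_rate > 0:
            lag = rng.exponential(1.0 / cfg.preservation_rate)
        else:
            lag = 0.0
        fad = min(tip_age + lag, parent_age)
        fad = max(fad, tip_age)
        duration = rng.exponential(cfg.range_duration_mean)
        lad = max(fad - duration, tip_age - 0.5, 0.01)
        lad = min(lad, fad)
        ranges.append(StratRange(taxon=leaf.taxon.label, fad=float(fad), lad=float(lad)))
    return ranges


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    tree: DatedTree
    matrix: CharacterMatrix
    ranges: list[StratRange]
    groups: dict[str, str]
    config: SimulationConfig


def simulate_study(cfg: "SimulationConfig | None" = None) -> SyntheticStudy:
    """Generate a full synthetic study bundle (tree, matrix, ranges, groups)."""
    cfg = cfg or SimulationConfig()
    tree = simulate_dated_tree(cfg)
    groups = assign_groups(tree)
    complete = simulate_characters(tree, cfg, groups=groups)
    matrix = apply_missingness(complete, cfg)
    ranges = simulate_ranges(tree, cfg)
    return SyntheticStudy(tree=tree, matrix=matrix, ranges=ranges, groups=groups,
                          config=cfg)
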