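"""Time-calibration of a tree topology from stratigraphic first appearances.

Three standard a-posteriori calibration variants are provided:

``basic``
    Each node is as young as its oldest descendant first appearance (FAD);
    zero-length branches are allowed.
``mbl``
    Minimum branch length: after the basic dating, every branch (terminal
    and internal) is forced to at least ``mbl`` Myr by pushing ancestral
    nodes older.
``equal``
    Zero-length branches absorb time from the nearest ancestral branch
    with positive duration, shared equally along the subtending path; the
    root is first extended ``root_buffer`` Myr beyond the basic root age
    so the most basal zero-length chains have time to draw on.

Tips are dated at their FAD: changes along a terminal branch are taken to
have accrued before the taxon's first documented occurrence.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

from morphorates.io_core import DatedTree, StratRange


def calibrate_tree(
    topology: DatedTree,
    ranges: Iterable[StratRange],
    method: str = "basic",
    mbl: float = 1.0,
    root_buffer: float = 0.0,
) -> DatedTree:
    """Date a rooted topology so that branch lengths are durations in Myr.

    Parameters
    ----------
    topology
        Rooted tree; existing branch lengths are ignored.  Polytomies are
        treated as hard.
    ranges
        One :class:`StratRange` per tip (FADs are used for dating).
    method
        ``"basic"``, ``"mbl"`` or ``"equal"`` (see module docstring).
    mbl
        Minimum branch duration in Myr (``method="mbl"`` only).
    root_buffer
        Myr added above the oldest FAD for the root age.  For ``"equal"``
        a positive buffer guarantees strictly positive branches even in
        the fully degenerate case of identical FADs.
    """
    if method not in ("basic", "mbl", "equal"):
        raise ValueError(f"unknown calibration method {method!r}")
    fad = {r.taxon: r.fad for r in ranges}
    out = topology.clone()
    tree = out.tree
    missing = [l for l in out.tip_labels if l not in fad]
    if missing:
        raise ValueError(f"tips without a first-appearance date: {missing}")

    age: dict[dendropy.Node, float] = {}
    # basic pass (postorder): node age = oldest descendant FAD
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            age[node] = fad[node.taxon.label]
        else:
            age[node] = max(age[c] for c in node.child_nodes())

    root = tree.seed_node
    if method == "mbl":
        if mbl <= 0:
            raise ValueError("mbl must be positive")
        for node in tree.postorder_node_iter():
            if not node.is_leaf():
                age[node] = max(age[node], max(age[c] + mbl for c in node.child_nodes()))
        age[root] = age[root] + root_buffer
    elif method == "basic":
        age[root] = age[root] + root_buffer
    else:  # equal
        age[root] = age[root] + root_buffer
        _spread_zero_branches(tree, age)

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            dur = age[node.parent_node] - age[node]
            if dur < -1e-9:
                raise RuntimeError(
                    "internal error: negative branch duration after calibration"
                )
            node.edge.length = max(dur, 0.0)
    root.edge.length = None
    return DatedTree(tree=tree, root_age=age[root])


def _spread_zero_branches(tree: dendropy.Tree, age: dict) -> None:
    """Re-space node ages so zero-duration branches share ancestral time.

    For each maximal chain of zero-duration branches (preorder), the
    nearest ancestral branch with positive duration is located and the
    nodes along the chain are spaced evenly between that branch's origin
    and the chain's bottom.  Raising a node's age never violates another
    branch's parent-older-than-child constraint, so a single preorder
    sweep, repeated until stable, suffices.
    """
    changed = True
    guard = 0
    while changed and guard < 1000:
        changed = False
        guard += 1
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None or age[parent] - age[node] > 1e-12:
                continue
            # walk up to the nearest strictly positive branch
            path = [node, parent]
            top = parent
            while top.parent_node is not None and age[top.parent_node] - age[top] <= 1e-12:
                top = top.parent_node
                path.append(top)
            anchor = top.parent_node
            if anchor is None:
                continue  # root-adjacent chain with no buffer to draw on
            # evenly space path nodes between age[anchor] and age[node]
            span = age[anchor] - age[node]
            if span <= 1e-12:
                continue
            k = len(path)  # number of branches being re-spaced
            for step, nd in enumerate(reversed(path[1:]), start=1):
                new_age = age[anchor] - span * step / k
                if abs(new_age - age[nd]) > 1e-12:
                    age[nd] = new_age
                    changed = True
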