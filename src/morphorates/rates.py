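"""Per-branch character change counts, corrected rates and heterogeneity tests.

Change counts come from unordered-state (Fitch) parsimony.  Each character
is optimized by dynamic programming over states (unit-cost Sankoff, which
equals Fitch on binary trees and handles polytomies, polymorphisms and
missing cells uniformly), then ancestral states are resolved in preorder
under either

- **ACCTRAN** (accelerated transformation): when placing a change on the
  current branch or deeper in the subtree costs the same, change now —
  changes accumulate as close to the root as possible;
- **DELTRAN** (delayed transformation): in the same situation keep the
  parent's state — changes are deferred tipward.

Remaining ties are broken toward the lowest state index.  Under both
conventions the summed changes per character equal the parsimony length.

Rates are corrected changes per Myr.  Missing data deflate observable
change counts, so raw counts are divided by the fraction of characters
scorable on the branch: for a terminal branch, the fraction of characters
coded for that tip; for an internal branch, the fraction of characters
coded by at least one tip on each side of the branch (the states at both
endpoints are then constrained by data).

Rate homogeneity is tested with likelihood-ratio statistics under a
Poisson model for the (corrected, real-valued) change count of each
branch with mean rate x duration: a global test of one shared rate
against per-branch rates, and per-branch tests of one branch against the
pooled rest, with Benjamini-Hochberg control across branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.stats

from morphorates.io_core import CharacterMatrix, DatedTree, TimeBins

logger = logging.getLogger(__name__)

_INF = np.inf


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class BranchChangeSet:
    """Per-branch change counts (and, after correction, rates).

    ``table`` is indexed by a stable branch id (the head node's taxon
    label for terminal branches, ``nodeK`` in preorder for internal ones)
    with columns ``raw_changes``, ``duration``, ``terminal`` and, when
    computed, ``scorable_fraction``, ``corrected_changes``, ``rate``,
    ``log10_rate``, ``excluded``.
    """

    tree: DatedTree
    optimization: str
    table: pd.DataFrame
    per_character_length: np.ndarray
    branch_ids: dict[int, str] = field(default_factory=dict)  # id(node) -> branch id

    @property
    def total_changes(self) -> float:
        return float(self.table["raw_changes"].sum())

    def included(self) -> pd.DataFrame:
        """Branches retained for rate analyses (positive duration and rate)."""
        if "excluded" not in self.table.columns:
            raise ValueError("call branch_rates() first")
        return self.table[~self.table["excluded"]]


@dataclass
class RateTestResult:
    """Global and per-branch likelihood-ratio tests of rate equality."""

    global_statistic: float
    global_df: int
    global_p: float
    per_branch: pd.DataFrame  # index branch id; statistic, p, p_adjusted, flag
    alpha: float


# ---------------------------------------------------------------------------
# Parsimony optimization
# ---------------------------------------------------------------------------


def _node_ids(t: DatedTree) -> dict[int, str]:
    ids: dict[int, str] = {}
    k = 0
    for node in t.tree.preorder_node_iter():
        if node.is_leaf():
            ids[id(node)] = node.taxon.label
        else:
            k += 1
            ids[id(node)] = f"node{k}"
    return ids


def _tip_cost_array(
    m: CharacterMatrix, label: str, n_states: int, alphabet: list[int]
) -> np.ndarray:
    """Unit-cost Sankoff tip costs, shape (n_states, n_characters)."""
    row = m.row(label)
    cost = np.full((n_states, m.n_characters), _INF)
    for j, cell in enumerate(row):
        if cell is None:
            cost[: alphabet[j], j] = 0.0
        else:
            for s in cell:
                cost[s, j] = 0.0
    return cost


def fitch_optimize(
    t: DatedTree, m: CharacterMatrix, opt: str = "acctran"
) -> BranchChangeSet:
    """Minimal per-branch state changes under ACCTRAN or DELTRAN.

    Characters are treated as unordered multistate; missing cells as the
    full state set, polymorphic cells as their member set.  The summed
    changes of each character equal its parsimony length for either
    optimization.
    """
    if opt not in ("acctran", "deltran"):
        raise ValueError("opt must be 'acctran' or 'deltran'")
    t.check_against_matrix(m)
    alphabet = [max(a, 1) for a in m.alphabet_sizes()]
    n_states = max(alphabet)
    n_chars = m.n_characters
    cols = np.arange(n_chars)

    # --- down pass: unit-cost Sankoff ------------------------------------
    cost: dict[int, np.ndarray] = {}
    for node in t.tree.postorder_node_iter():
        if node.is_leaf():
            cost[id(node)] = _tip_cost_array(m, node.taxon.label, n_states, alphabet)
        else:
            total = np.zeros((n_states, n_chars))
            for child in node.child_nodes():
                c = cost[id(child)]
                total += np.minimum(c, c.min(axis=0)[None, :] + 1.0)
            # states outside a character's alphabet stay unreachable
            for j in range(n_chars):
                total[alphabet[j]:, j] = _INF
            cost[id(node)] = total

    root = t.tree.seed_node
    per_char_length = cost[id(root)].min(axis=0)

    # --- preorder resolution ---------------------------------------------
    state: dict[int, np.ndarray] = {id(root): np.argmin(cost[id(root)], axis=0)}
    changes: dict[int, np.ndarray] = {}
    for node in t.tree.preorder_node_iter():
        parent_state = state[id(node)]
        for child in node.child_nodes():
            c = cost[id(child)]
            stay_cost = c[parent_state, cols]
            masked = c.copy()
            masked[parent_state, cols] = _INF
            move_state = np.argmin(masked, axis=0)
            move_cost = masked[move_state, cols] + 1.0
            if opt == "acctran":
                do_move = move_cost <= stay_cost
            else:
                do_move = move_cost < stay_cost
            child_state = np.where(do_move, move_state, parent_state)
            state[id(child)] = child_state
            changes[id(child)] = (child_state != parent_state).astype(float)

    # --- assemble table ----------------------------------------------------
    ids = _node_ids(t)
    rows = []
    for edge in t.branches():
        node = edge.head_node
        rows.append(
            {
                "branch": ids[id(node)],
                "raw_changes": float(changes[id(node)].sum()),
                "duration": float(edge.length) if edge.length is not None else np.nan,
                "terminal": node.is_leaf(),
            }
        )
    table = pd.DataFrame(rows).set_index("branch")
    return BranchChangeSet(
        tree=t,
        optimization=opt,
        table=table,
        per_character_length=per_char_length,
        branch_ids=ids,
    )


# ---------------------------------------------------------------------------
# Missing-data correction and rates
# ---------------------------------------------------------------------------


def completeness_correct(
    changes: BranchChangeSet, m: CharacterMatrix, t: "DatedTree | None" = None
) -> BranchChangeSet:
    """Scale raw change counts by per-branch character scorability.

    ``scorable_fraction`` for a terminal branch is the fraction of
    characters coded for its tip; for an internal branch, the fraction of
    characters coded by at least one tip inside and at least one tip
    outside the subtree it subtends.  ``corrected = raw / fraction``.
    Branches with fraction 0 are excluded with a warning.
    """
    t = t or changes.tree
    scored = m.scored_mask()
    tip_row = {label: i for i, label in enumerate(m.taxon_labels)}
    n_chars = m.n_characters
    total_scored = scored.any(axis=0)

    inside: dict[int, np.ndarray] = {}
    for node in t.tree.postorder_node_iter():
        if node.is_leaf():
            inside[id(node)] = scored[tip_row[node.taxon.label]]
        else:
            acc = np.zeros(n_chars, dtype=bool)
            for child in node.child_nodes():
                acc |= inside[id(child)]
            inside[id(node)] = acc

    fractions = {}
    for edge in t.branches():
        node = edge.head_node
        bid = changes.branch_ids[id(node)]
        if node.is_leaf():
            frac = scored[tip_row[node.taxon.label]].mean()
        else:
            # characters with data on both sides of the branch
            both = inside[id(node)] & _outside_scored(t, node, scored, tip_row)
            frac = both.mean()
        fractions[bid] = float(frac)

    table = changes.table.copy()
    table["scorable_fraction"] = pd.Series(fractions)
    zero = table["scorable_fraction"] <= 0
    if zero.any():
        logger.warning(
            "branches with scorable_fraction 0 excluded: %s",
            list(table.index[zero]),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["corrected_changes"] = np.where(
            zero, np.nan, table["raw_changes"] / table["scorable_fraction"]
        )
    return BranchChangeSet(
        tree=changes.tree,
        optimization=changes.optimization,
        table=table,
        per_character_length=changes.per_character_length,
        branch_ids=changes.branch_ids,
    )


def _outside_scored(t, node, scored, tip_row) -> np.ndarray:
    """Characters coded by at least one tip outside ``node``'s subtree."""
    subtree = {id(l) for l in node.leaf_iter()}
    acc = np.zeros(scored.shape[1], dtype=bool)
    for leaf in t.tree.leaf_node_iter():
        if id(leaf) not in subtree:
            acc |= scored[tip_row[leaf.taxon.label]]
    return acc


def branch_rates(changes: BranchChangeSet) -> BranchChangeSet:
    """Rates in changes/Myr with exclusion flags and log10 transform.

    Branches with non-positive duration, undefined corrected counts, or a
    zero rate are flagged ``excluded`` (zero-rate branches carry no rate
    information on the log scale and are left out of downstream rate
    analyses).
    """
    table = changes.table.copy()
    if "corrected_changes" not in table.columns:
        table["scorable_fraction"] = 1.0
        table["corrected_changes"] = table["raw_changes"]
    ok_duration = table["duration"] > 0
    if (~ok_duration).any():
        logger.warning(
            "branches with zero/undefined duration excluded: %s",
            list(table.index[~ok_duration]),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["rate"] = np.where(
            ok_duration, table["corrected_changes"] / table["duration"], np.nan
        )
    table["excluded"] = (
        ~ok_duration | table["rate"].isna() | (table["rate"] <= 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["log10_rate"] = np.where(
            table["excluded"], np.nan, np.log10(table["rate"])
        )
    return BranchChangeSet(
        tree=changes.tree,
        optimization=changes.optimization,
        table=table,
        per_character_length=changes.per_character_length,
        branch_ids=changes.branch_ids,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio rate tests
# ---------------------------------------------------------------------------


def _poisson_lr_term(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Per-observation deviance contribution 2*(x ln(x/mu) - x + mu)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(x / mu), 0.0)
    return 2.0 * (term - x + mu)


def rate_equality_tests(changes: BranchChangeSet, alpha: float = 0.05) -> RateTestResult:
    """LRTs of rate equality under a Poisson change-count model.

    Raw branch change counts are modelled as Poisson with mean
    ``rate x exposure``, where a branch's exposure is its duration times
    its scorable fraction — the missing-data correction enters the
    likelihood as an exposure offset rather than by rescaling counts
    (rescaled counts are no longer Poisson and their inflated variance
    distorts the tests; the branch *rate* estimate ``raw / exposure`` is
    identical to corrected changes per Myr either way).

    Global test: one shared rate (null) against a saturated per-branch
    rate model; statistic ``2 (lnL1 - lnL0)``, chi-square with
    ``branches - 1`` df.  Per-branch tests: branch *i* with its own rate
    against the pooled rest, 1 df, Benjamini-Hochberg adjusted; branches
    are flagged ``high`` or ``low`` by the sign of their rate relative to
    the pooled rate when the adjusted p falls below ``alpha``.
    """
    table = changes.included()
    x = table["raw_changes"].to_numpy(dtype=float)
    if "scorable_fraction" in table.columns:
        frac = table["scorable_fraction"].to_numpy(dtype=float)
    else:
        frac = np.ones(len(x))
    dur = table["duration"].to_numpy(dtype=float)
    exposure = dur * frac
    n = len(x)
    if n < 2:
        raise ValueError("need at least two branches with positive duration")
    pooled_rate = x.sum() / exposure.sum()

    global_stat = float(_poisson_lr_term(x, pooled_rate * exposure).sum())
    global_df = n - 1
    global_p = float(scipy.stats.chi2.sf(global_stat, global_df))

    stats = np.empty(n)
    for i in range(n):
        x_rest = x.sum() - x[i]
        e_rest = exposure.sum() - exposure[i]
        # alternative: own rate for i, pooled rate for the rest
        stat = (
            _poisson_lr_term(np.array([x[i]]), pooled_rate * exposure[i]).sum()
            + _poisson_lr_term(np.array([x_rest]), pooled_rate * e_rest).sum()
        )
        stats[i] = stat
    pvals = scipy.stats.chi2.sf(stats, 1)
    p_adj = _benjamini_hochberg(pvals)
    rate = x / exposure  # = corrected changes per Myr
    flag = np.where(
        p_adj < alpha, np.where(rate > pooled_rate, "high", "low"), "none"
    )
    per_branch = pd.DataFrame(
        {
            "statistic": stats,
            "p": pvals,
            "p_adjusted": p_adj,
            "rate": rate,
            "flag": flag,
        },
        index=table.index,
    )
    return RateTestResult(
        global_statistic=global_stat,
        global_df=global_df,
        global_p=global_p,
        per_branch=per_branch,
        alpha=alpha,
    )


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Rates through time
# ---------------------------------------------------------------------------


def rates_by_interval(
    changes: BranchChangeSet, bins: TimeBins
) -> dict[str, np.ndarray]:
    """Assign every included branch's rate to all intervals it crosses.

    A branch spanning [head age, parent age] contributes its single rate
    to each bin [end, start) it overlaps with positive duration.  Bins
    with no branches map to empty arrays.
    """
    ages = changes.tree.node_ages()
    table = changes.included()
    spans: dict[str, tuple[float, float]] = {}
    for edge in changes.tree.branches():
        bid = changes.branch_ids[id(edge.head_node)]
        if bid in table.index:
            head_age = ages[edge.head_node]
            spans[bid] = (head_age, ages[edge.head_node.parent_node])
    out: dict[str, list[float]] = {label: [] for label in bins.labels}
    for bid, (young, old) in spans.items():
        rate = float(table.loc[bid, "rate"])
        for label, start, end in bins:
            if min(old, start) - max(young, end) > 1e-12:
                out[label].append(rate)
    return {label: np.asarray(v) for label, v in out.items()}


def rate_time_regression(
    interval_rates: dict[str, np.ndarray],
    bins: TimeBins,
    log10: bool = True,
) -> dict[str, float]:
    """OLS of (log10) rate on interval midpoint plus Kendall's tau.

    Each branch-in-bin observation is paired with its bin midpoint (Ma).
    Empty bins are dropped.  Returns slope, intercept, tau and the
    tau p-value (normal approximation, tie-corrected).
    """
    mids = dict(zip(bins.labels, bins.midpoints))
    xs, ys = [], []
    for label, rates in interval_rates.items():
        for r in rates:
            if r <= 0:
                continue
            xs.append(mids[label])
            ys.append(np.log10(r) if log10 else r)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 3:
        raise ValueError("need at least three rate observations")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        tau, p = 0.0, 1.0
    else:
        tau, p = scipy.stats.kendalltau(x, y, method="asymptotic")
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "tau": float(tau),
        "p": float(p),
        "n": int(len(x)),
    }


def rates_newick(changes: BranchChangeSet) -> str:
    """Newick with branch lengths replaced by rates (NaN rates as 0)."""
    tree = changes.tree.tree.clone(depth=1)
    table = changes.table
    ids = _node_ids(DatedTree(tree))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bid = ids[id(node)]
        rate = table.loc[bid, "rate"] if "rate" in table.columns else np.nan
        node.edge.length = 0.0 if pd.isna(rate) else float(rate)
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
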