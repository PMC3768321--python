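"""Parsimony change counts, corrected rates and heterogeneity tests."""

import itertools

import dendropy
import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from morphorates.io_core import DatedTree, TimeBins, tree_from_newick
from morphorates.rates import (
    _poisson_lr_term,
    branch_rates,
    completeness_correct,
    fitch_optimize,
    rate_equality_tests,
    rate_time_regression,
    rates_by_interval,
    rates_newick,
)

from .conftest import make_matrix


def brute_force_length(t: DatedTree, m, char_j: int) -> int:
    """Minimal changes by exhaustive enumeration of internal-node states."""
    internals = [n for n in t.tree.preorder_node_iter() if not n.is_leaf()]
    tip_cells = {l: m.row(l)[char_j] for l in t.tip_labels}
    n_states = max(
        (max(c) for c in tip_cells.values() if c is not None), default=0
    ) + 1
    best = np.inf
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        states = dict(zip((id(n) for n in internals), assign))
        total = 0
        for node in t.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            ps = states[id(parent)]
            if node.is_leaf():
                cell = tip_cells[node.taxon.label]
                if cell is not None and ps not in cell:
                    total += 1
            elif states[id(node)] != ps:
                total += 1
        best = min(best, total)
    return int(best)


class TestFitch:
    def test_single_synapomorphy_on_internal_branch(self, balanced_quartet):
        m = make_matrix("ABCD", [[0], [0], [1], [1]])
        for opt in ("acctran", "deltran"):
            cs = fitch_optimize(balanced_quartet, m, opt)
            internal = cs.table[~cs.table["terminal"]]
            assert cs.per_character_length[0] == 1
            assert internal["raw_changes"].sum() == 1

    def test_autapomorphy_on_terminal_branch_both_opts(self, balanced_quartet):
        m = make_matrix("ABCD", [[1], [0], [0], [0]])
        for opt in ("acctran", "deltran"):
            cs = fitch_optimize(balanced_quartet, m, opt)
            assert cs.table.loc["A", "raw_changes"] == 1
            assert cs.total_changes == 1

    def test_acctran_rootward_deltran_tipward(self, balanced_quartet):
        # A=1 with B ambiguous: ACCTRAN pulls the change onto the deeper
        # branch, DELTRAN defers it to the terminal branch
        m = make_matrix("ABCD", [[1], [None], [0], [0]])
        acc = fitch_optimize(balanced_quartet, m, "acctran")
        delt = fitch_optimize(balanced_quartet, m, "deltran")
        assert acc.total_changes == delt.total_changes == 1
        assert acc.table.loc["A", "raw_changes"] == 0
        assert delt.table.loc["A", "raw_changes"] == 1

    def test_constant_and_all_missing_characters_contribute_zero(
        self, balanced_quartet
    ):
        m = make_matrix("ABCD", [[0, None], [0, None], [0, None], [0, None]])
        cs = fitch_optimize(balanced_quartet, m, "acctran")
        assert cs.total_changes == 0

    @pytest.mark.parametrize("opt", ["acctran", "deltran"])
    def test_total_changes_match_exhaustive_parsimony(self, opt, rng):
        import random

        pyrng = random.Random(7)
        for _ in range(12):
            n_tips = pyrng.randint(3, 6)
            labels = [f"T{i}" for i in range(n_tips)]
            tns = dendropy.TaxonNamespace(labels)
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
                rng=pyrng, taxon_namespace=tns,
            )
            for e in tree.preorder_edge_iter():
                e.length = 1.0
            t = DatedTree(tree)
            rows = []
            for _ in range(n_tips):
                row = []
                for _ in range(3):
                    u = pyrng.random()
                    if u < 0.15:
                        row.append(None)
                    elif u < 0.3:
                        row.append(frozenset(pyrng.sample(range(4), 2)))
                    else:
                        row.append(pyrng.randrange(4))
                rows.append(row)
            m = make_matrix(labels, rows)
            cs = fitch_optimize(t, m, opt)
            for j in range(3):
                assert cs.per_character_length[j] == brute_force_length(t, m, j)
            assert cs.total_changes == cs.per_character_length.sum()

    def test_polytomy_handled(self):
        # on a 4-tip star, states 0011 need two changes whatever the root
        t = tree_from_newick("(A:1,B:1,C:1,D:1);")
        m = make_matrix("ABCD", [[0], [0], [1], [1]])
        cs = fitch_optimize(t, m, "acctran")
        assert cs.per_character_length[0] == 2
        assert cs.total_changes == 2


class TestCompletenessCorrection:
    def test_fully_coded_matrix_is_identity(self, balanced_quartet):
        m = make_matrix("ABCD", [[0, 1], [0, 0], [1, 1], [1, 0]])
        cs = completeness_correct(fitch_optimize(balanced_quartet, m, "acctran"), m)
        assert np.allclose(cs.table["scorable_fraction"], 1.0)
        assert np.allclose(cs.table["corrected_changes"], cs.table["raw_changes"])

    def test_terminal_fraction_scales_counts(self, balanced_quartet):
        # tip A scored for 2 of 4 characters: corrected = raw / 0.5
        m = make_matrix(
            "ABCD",
            [[1, 1, None, None], [0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 1, 1]],
        )
        cs = completeness_correct(fitch_optimize(balanced_quartet, m, "acctran"), m)
        assert cs.table.loc["A", "scorable_fraction"] == pytest.approx(0.5)
        assert cs.table.loc["A", "corrected_changes"] == pytest.approx(
            2 * cs.table.loc["A", "raw_changes"]
        )

    def test_halving_scored_characters_doubles_correction(self, balanced_quartet):
        full = make_matrix("ABCD", [[1] * 4, [0] * 4, [0] * 4, [0] * 4])
        half = make_matrix(
            "ABCD", [[1, 1, None, None], [0] * 4, [0] * 4, [0] * 4]
        )
        cs_full = completeness_correct(
            fitch_optimize(balanced_quartet, full, "acctran"), full
        )
        cs_half = completeness_correct(
            fitch_optimize(balanced_quartet, half, "acctran"), half
        )
        ratio_full = (
            cs_full.table.loc["A", "corrected_changes"]
            / cs_full.table.loc["A", "raw_changes"]
        )
        ratio_half = (
            cs_half.table.loc["A", "corrected_changes"]
            / cs_half.table.loc["A", "raw_changes"]
        )
        assert ratio_half == pytest.approx(2 * ratio_full)

    def test_internal_branch_needs_data_on_both_sides(self, balanced_quartet):
        # character 2 is coded only inside the (C,D) clade, so it is not
        # scorable on the internal branches
        m = make_matrix(
            "ABCD", [[0, None], [0, None], [1, 0], [1, 1]]
        )
        cs = completeness_correct(fitch_optimize(balanced_quartet, m, "acctran"), m)
        internal = cs.table[~cs.table["terminal"]]
        assert np.allclose(internal["scorable_fraction"], 0.5)


class TestRates:
    def test_rate_and_log10(self, balanced_quartet):
        m = make_matrix("ABCD", [[1, 1], [0, 0], [0, 0], [0, 0]])
        cs = branch_rates(fitch_optimize(balanced_quartet, m, "acctran"))
        assert cs.table.loc["A", "rate"] == pytest.approx(2.0)
        assert cs.table.loc["A", "log10_rate"] == pytest.approx(np.log10(2.0))

    def test_zero_change_branches_flagged_excluded(self, balanced_quartet):
        m = make_matrix("ABCD", [[1], [0], [0], [0]])
        cs = branch_rates(fitch_optimize(balanced_quartet, m, "acctran"))
        assert bool(cs.table.loc["B", "excluded"])
        assert not bool(cs.table.loc["A", "excluded"])

    def test_rates_scale_inversely_with_durations(self):
        m = make_matrix("ABCD", [[1, 1], [0, 1], [0, 0], [0, 0]])
        t1 = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_from_newick("((A:2,B:2):2,(C:2,D:2):2);")
        r1 = branch_rates(fitch_optimize(t1, m, "acctran")).included()["rate"]
        r2 = branch_rates(fitch_optimize(t2, m, "acctran")).included()["rate"]
        assert np.allclose(r1.to_numpy(), 2 * r2.to_numpy())

    def test_rates_newick_emits_rate_lengths(self, balanced_quartet):
        m = make_matrix("ABCD", [[1, 1], [0, 0], [0, 0], [0, 0]])
        cs = branch_rates(fitch_optimize(balanced_quartet, m, "acctran"))
        s = rates_newick(cs)
        assert "A:2.0" in s


class TestRateEqualityLRT:
    def test_identical_branches_give_null_result(self):
        t = tree_from_newick("((A:2,B:2):2,(C:2,D:2):2);")
        m = make_matrix("ABCD", [[1, 0], [0, 1], [0, 0], [0, 0]])
        cs = branch_rates(fitch_optimize(t, m, "acctran"))
        res = rate_equality_tests(cs)
        assert res.global_p > 0.05
        assert (res.per_branch["flag"] == "none").all()

    def test_statistic_matches_numeric_optimization(self, rng):
        # per-branch LRT closed form vs direct likelihood maximization
        x = rng.poisson(3.0, size=6).astype(float) + 1.0
        expo = rng.uniform(0.5, 4.0, size=6)

        def loglik(rates, xs, es):
            mu = rates * es
            return float(np.sum(xs * np.log(mu) - mu))

        pooled = x.sum() / expo.sum()
        for i in range(6):
            x_rest, e_rest = x.sum() - x[i], expo.sum() - expo[i]
            stat_closed = (
                _poisson_lr_term(np.array([x[i]]), pooled * expo[i]).sum()
                + _poisson_lr_term(np.array([x_rest]), pooled * e_rest).sum()
            )
            ll_null = loglik(np.full(2, pooled), np.array([x[i], x_rest]),
                             np.array([expo[i], e_rest]))
            opt = scipy.optimize.minimize(
                lambda v: -loglik(np.array(v), np.array([x[i], x_rest]),
                                  np.array([expo[i], e_rest])),
                x0=[pooled, pooled],
                bounds=[(1e-9, None)] * 2,
            )
            stat_numeric = 2.0 * (-opt.fun - ll_null)
            assert stat_closed == pytest.approx(stat_numeric, abs=1e-5)

    def test_global_p_calibrated_under_poisson_null(self, rng):
        # simulate homogeneous Poisson counts on fixed exposures and check
        # the size of the global test at alpha = 0.05
        expo = rng.uniform(0.5, 10.0, size=30)
        lam = 1.2
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            x = rng.poisson(lam * expo).astype(float)
            pooled = x.sum() / expo.sum()
            stat = _poisson_lr_term(x, pooled * expo).sum()
            p = scipy.stats.chi2.sf(stat, len(x) - 1)
            rejections += p < 0.05
        size = rejections / n_sims
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sims)
        assert size < 0.05 + ci + 0.02

    def test_too_few_branches_rejected(self):
        t = tree_from_newick("(A:1,B:0);")
        m = make_matrix("AB", [[1], [0]])
        cs = branch_rates(fitch_optimize(t, m, "acctran"))
        with pytest.raises(ValueError):
            rate_equality_tests(cs)


class TestRatesThroughTime:
    BINS = TimeBins([("t1", 12.0, 8.0), ("t2", 8.0, 4.0), ("t3", 4.0, 0.0)])

    def _changeset(self):
        t = tree_from_newick("((A:5,B:1):4,C:10);")
        t.root_age = 10.0
        m = make_matrix("ABC", [[1, 0], [0, 0], [0, 1]])
        return branch_rates(fitch_optimize(t, m, "acctran"))

    def test_branch_rate_assigned_to_every_crossed_bin(self):
        cs = self._changeset()
        by_bin = rates_by_interval(cs, self.BINS)
        # branch C spans 10 -> 0 Ma and crosses all three bins
        c_rate = cs.table.loc["C", "rate"]
        for label in ("t1", "t2", "t3"):
            assert c_rate in by_bin[label]
        # the zero-change branch B carries no rate and enters no bin
        assert cs.table.loc["B", "excluded"]

    def test_empty_bins_stay_empty(self):
        cs = self._changeset()
        bins = TimeBins([("pre", 40.0, 30.0), ("cov", 12.0, 0.0)])
        by_bin = rates_by_interval(cs, bins)
        assert len(by_bin["pre"]) == 0 and len(by_bin["cov"]) > 0

    def test_regression_constant_rates_flat(self):
        bins = self.BINS
        rates = {"t1": np.array([2.0, 2.0]), "t2": np.array([2.0]),
                 "t3": np.array([2.0, 2.0])}
        res = rate_time_regression(rates, bins)
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)
        assert res["tau"] == 0.0

    def test_regression_monotone_rates_give_tau_one(self):
        bins = self.BINS
        rates = {"t1": np.array([8.0]), "t2": np.array([4.0]), "t3": np.array([2.0])}
        res = rate_time_regression(rates, bins)
        assert res["tau"] == pytest.approx(1.0)

    def test_kendall_matches_pair_counting_oracle(self, rng):
        x = rng.uniform(0, 10, size=12)
        y = rng.uniform(0, 10, size=12)
        conc = disc = 0
        for i in range(12):
            for j in range(i + 1, 12):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / (12 * 11 / 2)
        tau, _ = scipy.stats.kendalltau(x, y)
        assert tau == pytest.approx(expected)
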