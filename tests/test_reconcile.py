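import numpy as np
import pytest

import cophylokit as ck
from conftest import make_congruent_pair, random_tanglegram
from cophylokit.reconcile import (
    CostScheme,
    Reconciliation,
    ReconciliationOptions,
    check_chronology,
    cospeciation_significance,
    estimate_costs,
    flag_implausible,
    reconcile,
    reconciliation_quality,
)
from oracles import brute_force_min_cost, chronology_feasible_by_enumeration


def internal_count(tree):
    return len(tree.internal_nodes())


class TestReconcileDP:
    def test_perfect_congruence(self, three_leaf_pair):
        host, parasite, links = three_leaf_pair
        rec = reconcile(host, parasite, links, CostScheme(0, 1, 1, 2))
        assert (rec.n_cosp, rec.n_sort, rec.n_dup, rec.n_switch) == (2, 0, 0, 0)
        assert rec.total_cost == 0

    def test_small_incongruent_matches_enumeration(self):
        host = ck.parse_newick("((A,B),C);")
        parasite = ck.parse_newick("((a,c),b);")
        links = ck.HostParasiteLinks.from_pairs([("a", "A"), ("b", "B"), ("c", "C")])
        costs = CostScheme(0, 1, 1, 1)
        rec = reconcile(host, parasite, links, costs)
        oracle = brute_force_min_cost(host, parasite, links, costs)
        assert rec.total_cost == pytest.approx(oracle)

    def test_dp_equals_bruteforce_on_random_tanglegrams(self):
        """DP minimum equals exhaustive enumeration on 100 small cases."""
        rng = np.random.default_rng(2024)
        for rep in range(100):
            host, parasite, links = random_tanglegram(rng)
            costs = CostScheme(*np.round(rng.uniform(0, 2, size=4), 3))
            for root_to_root in (True, False):
                opts = ReconciliationOptions(root_to_root=root_to_root)
                rec = reconcile(host, parasite, links, costs, opts)
                oracle = brute_force_min_cost(
                    host, parasite, links, costs, root_to_root=root_to_root
                )
                assert rec.total_cost == pytest.approx(oracle), (
                    f"rep {rep}: DP {rec.total_cost} != brute force {oracle}"
                )

    def test_event_conservation(self):
        rng = np.random.default_rng(7)
        for rep in range(30):
            host, parasite, links = random_tanglegram(rng, 6, 6)
            rec = reconcile(host, parasite, links, CostScheme(0, 1, 1, 2))
            assert rec.n_cosp + rec.n_dup + rec.n_switch == internal_count(parasite)

    def test_switch_cost_monotonicity(self):
        rng = np.random.default_rng(99)
        for rep in range(25):
            host, parasite, links = random_tanglegram(rng, 5, 5)
            n_w = [
                reconcile(host, parasite, links, CostScheme(0.1, 0.3, 0.4, w)).n_switch
                for w in (0.2, 0.5, 1.0, 2.0)
            ]
            assert n_w == sorted(n_w, reverse=True)

    def test_deterministic_output(self):
        rng = np.random.default_rng(5)
        host, parasite, links = random_tanglegram(rng, 5, 5)
        costs = CostScheme(0.2, 0.3, 0.25, 0.25)
        a = reconcile(host, parasite, links, costs)
        b = reconcile(host, parasite, links, costs)
        assert a.to_dict() == b.to_dict()

    def test_charge_dup_with_switch_increases_cost(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            host, parasite, links = random_tanglegram(rng, 5, 5)
            base = reconcile(host, parasite, links, CostScheme(0.5, 0.2, 0.7, 0.6))
            charged = reconcile(
                host, parasite, links, CostScheme(0.5, 0.2, 0.7, 0.6),
                ReconciliationOptions(charge_dup_with_switch=True),
            )
            assert charged.total_cost >= base.total_cost - 1e-12

    def test_unlinked_leaf_rejected(self):
        host = ck.parse_newick("(A,B);")
        parasite = ck.parse_newick("(a,b);")
        links = ck.HostParasiteLinks.from_pairs([("a", "A")])
        with pytest.raises(ValueError, match="no host link"):
            reconcile(host, parasite, links)

    def test_polytomy_requires_flag(self):
        host = ck.parse_newick("((A,B),C);")
        parasite = ck.parse_newick("(a,b,c);")
        links = ck.HostParasiteLinks.from_pairs([("a", "A"), ("b", "B"), ("c", "C")])
        with pytest.raises(ValueError, match="polytom"):
            reconcile(host, parasite, links)
        rec = reconcile(
            host, parasite, links, opts=ReconciliationOptions(allow_polytomies=True)
        )
        assert rec.polytomies_resolved

    def test_multi_host_leaf_split(self):
        host = ck.parse_newick("((A,B),C);")
        parasite = ck.parse_newick("(a,c);")
        links = ck.HostParasiteLinks.from_pairs(
            [("a", "A"), ("a", "B"), ("c", "C")]
        )
        rec = reconcile(host, parasite, links, CostScheme(0, 1, 1, 2))
        assert "a@A" in rec.mapping and "a@B" in rec.mapping

    def test_simulated_histories_recovered(self):
        """Inferred counts track the generating process (cosp-dominated)."""
        from scipy.stats import spearmanr

        true_all, inferred = [], []
        for i in range(50):
            host = ck.simulate_yule(10, 1.0, seed=300 + i, prefix="H")
            params = ck.SimParams(p_cosp=0.9, r_dup=0.4, r_switch=0.15, r_loss=0.1)
            try:
                sim = ck.simulate_cophylogeny(host, params, seed=400 + i)
            except RuntimeError:
                continue
            if sim.parasite.n_leaves < 3:
                continue
            rec = reconcile(sim.host, sim.parasite, sim.links, CostScheme(0, 1, 1, 2))
            for ev in ("cospeciation", "sorting", "duplication", "host_switch"):
                true_all.append(sim.tally[ev])
                inferred.append(rec.counts[ev])
        rho = spearmanr(true_all, inferred).statistic
        assert rho >= 0.7


class TestEstimateCosts:
    def test_identical_trees_favor_cospeciation(self):
        for seed in range(20):
            host, parasite, links = make_congruent_pair(6, seed=seed)
            scheme, rec, q, _ = estimate_costs(
                host, parasite, links, n_sets=60, seed=seed
            )
            norm = scheme.normalized()
            assert norm.cosp < min(norm.sort, norm.dup, norm.switch)

    def test_self_consistency_and_determinism(self):
        host, parasite, links = make_congruent_pair(6, seed=1)
        scheme, rec, q, ranked = estimate_costs(host, parasite, links, n_sets=50, seed=9)
        again = reconcile(host, parasite, links, scheme)
        assert again.total_cost == pytest.approx(rec.total_cost)
        assert again.counts == rec.counts
        scheme2, rec2, q2, _ = estimate_costs(host, parasite, links, n_sets=50, seed=9)
        assert scheme2 == scheme and q2 == q
        assert q == pytest.approx(reconciliation_quality(rec, scheme))


class TestPlausibilityFilter:
    def test_zero_switch_high_cost_rejected(self):
        # counts and estimated costs of a zero-switch solution whose
        # switch cost soaked up nearly the whole budget
        rec = Reconciliation(
            mapping={}, events={}, switches=[],
            n_cosp=12, n_sort=51, n_dup=15, n_switch=0,
            total_cost=0.61, costs=CostScheme(0.017, 0.0040, 0.013, 0.97),
            quality=0.0054,
        )
        flagged, reason = flag_implausible(rec)
        assert flagged and "host-switch" in reason

    def test_balanced_solution_retained(self):
        rec = Reconciliation(
            mapping={}, events={}, switches=[],
            n_cosp=11, n_sort=33, n_dup=12, n_switch=4,
            total_cost=9.53, costs=CostScheme(0.25, 0.074, 0.20, 0.47),
            quality=0.04,
        )
        assert flag_implausible(rec) == (False, "plausible")

    def test_second_zero_switch_row_rejected(self):
        rec = Reconciliation(
            mapping={}, events={}, switches=[],
            n_cosp=10, n_sort=65, n_dup=17, n_switch=0,
            total_cost=0.032, costs=CostScheme(0.000998, 0.00017, 0.00067, 0.998),
            quality=0.018,
        )
        assert flag_implausible(rec)[0]

    def test_all_events_present_never_flagged(self):
        rec = Reconciliation(
            mapping={}, events={}, switches=[],
            n_cosp=1, n_sort=1, n_dup=1, n_switch=1,
            total_cost=1.0, costs=CostScheme(0.01, 0.01, 0.01, 0.97),
        )
        assert not flag_implausible(rec)[0]


class TestChronology:
    @staticmethod
    def _rec(switches):
        return Reconciliation(
            mapping={}, events={}, switches=switches,
            n_cosp=0, n_sort=0, n_dup=0, n_switch=len(switches),
            total_cost=0.0, costs=CostScheme(),
        )

    def test_no_switch_consistent(self):
        host = ck.parse_newick("((A,B),C);")
        assert check_chronology(host, self._rec([]))

    def test_single_cross_switch_consistent(self):
        host = ck.parse_newick("((A,B),(C,D));")
        rec = self._rec([("A", "C")])
        assert check_chronology(host, rec)
        assert chronology_feasible_by_enumeration(host, rec.switches)

    def test_two_switch_cycle_inconsistent(self):
        # a switch from the A-B clade into the edge above <C>, and one from
        # the C-D clade into the edge above <A>: each requires the other
        # clade's stem to predate its own crown - a cycle
        host = ck.parse_newick("((A,B),(C,D));")
        switches = [("A", "<C|2>"), ("C", "<A|2>")]
        assert not check_chronology(host, self._rec(switches))
        assert not chronology_feasible_by_enumeration(host, switches)

    def test_agreement_with_enumeration_on_random_cases(self):
        rng = np.random.default_rng(31)
        host = ck.parse_newick("(((A,B),(C,D)),((E,F),G));")
        vertices = ["A", "B", "C", "D", "E", "F", "G", "<A|2>", "<C|2>", "<E|2>", "<A|4>", "<E|3>"]
        for _ in range(40):
            k = int(rng.integers(1, 4))
            switches = []
            while len(switches) < k:
                s, t = rng.choice(len(vertices), size=2, replace=False)
                switches.append((vertices[s], vertices[t]))
            assert check_chronology(
                host, self._rec(switches)
            ) == chronology_feasible_by_enumeration(host, switches)

    def test_simulated_true_histories_always_consistent(self):
        """The generator only switches between contemporaneous branches, so
        the true switch log always passes the chronology check."""
        checked = 0
        for i in range(15):
            host = ck.simulate_yule(8, 1.0, seed=i, prefix="H")
            try:
                sim = ck.simulate_cophylogeny(
                    host, ck.SimParams(r_switch=0.8, r_loss=0.05), seed=50 + i
                )
            except RuntimeError:
                continue
            switches = [
                (ev["host"], ev["target"])
                for ev in sim.events
                if ev["type"] == "host_switch"
            ]
            if switches:
                checked += 1
                assert check_chronology(host, self._rec(switches))
        assert checked >= 5


class TestCospeciationSignificance:
    def test_congruent_trees_significant(self):
        host, parasite, links = make_congruent_pair(8, seed=3)
        obs, p = cospeciation_significance(host, parasite, links, n_rand=200, seed=0)
        assert obs == 7
        assert p <= 0.05

    def test_two_leaf_trees_trivial(self):
        host = ck.parse_newick("(A,B);")
        parasite = ck.parse_newick("(a,b);")
        links = ck.HostParasiteLinks.from_pairs([("a", "A"), ("b", "B")])
        obs, p = cospeciation_significance(host, parasite, links, n_rand=50, seed=0)
        assert p == 1.0

    def test_p_bounds(self):
        rng = np.random.default_rng(17)
        host, parasite, links = random_tanglegram(rng, 5, 5)
        n_rand = 99
        _, p = cospeciation_significance(host, parasite, links, n_rand=n_rand, seed=1)
        assert 1 / (n_rand + 1) <= p <= 1
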