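"""Pagel machinery: pruning likelihood, ML fitting, bootstrap test."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from pgtrait.annotation_io import ValidationError
from pgtrait.correlated_evolution import (
    RateModel,
    _pmats_2state,
    fit,
    mk_loglik,
    pagel_test,
)
from pgtrait.phylo_events import parse_newick
from pgtrait.synthetic_data import simulate_characters, simulate_tree


def brute_force_loglik(tree, tip_states, model, default_length=1.0):
    """Sum over all internal joint states with explicit matrix exponentials."""
    Q = model.generator()
    lengths = tree.branch_lengths(default_length)
    P = {v: expm(Q * lengths[v]) for v in range(tree.n_nodes) if v != tree.root}
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]

    def tip_options(lab):
        a, b = tip_states[lab]
        return [
            s
            for s in range(4)
            if (a is None or s // 2 == a) and (b is None or s % 2 == b)
        ]

    tips = list(tree.tip_id_of.items())
    total = 0.0
    for internal_assign in itertools.product(range(4), repeat=len(internal)):
        st = dict(zip(internal, internal_assign))
        for tip_assign in itertools.product(*(tip_options(lab) for lab, _ in tips)):
            st.update({tid: s for (_, tid), s in zip(tips, tip_assign)})
            p = 0.25
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                p *= P[v][st[tree.parent[v]], st[v]]
            total += p
    return math.log(total)


class TestLoglik:
    def test_symmetric_two_state_closed_form(self):
        # P(1 -> 1) over a branch of length ln(2)/2 at rate 1 each way
        t = math.log(2.0) / 2.0
        P = _pmats_2state(1.0, 1.0, np.array([t]))
        assert P[0, 1, 1] == pytest.approx((1 + math.exp(-2 * t)) / 2)
        assert P[0, 1, 1] == pytest.approx(0.75)

    def test_all_rates_zero_gives_root_prior_only(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        model = RateModel.dependent([0.0] * 8)
        tips = {lab: (1, 1) for lab in "ABCD"}
        assert mk_loglik(tree, tips, model) == pytest.approx(math.log(0.25))

    def test_matches_bruteforce_on_small_trees(self):
        rng = np.random.default_rng(2)
        for case in range(60):
            tree = simulate_tree(int(rng.integers(3, 7)), seed=case)
            kind = "independent" if case % 2 else "dependent"
            rates = rng.uniform(0.05, 3.0, 4 if kind == "independent" else 8)
            model = RateModel(kind, tuple(rates))
            hist = simulate_characters(tree, model, seed=case + 500)
            tips = dict(hist.tip_states)
            # occasionally blank one component to exercise ambiguity handling
            if case % 5 == 0:
                lab = tree.tip_labels[0]
                tips[lab] = (None, tips[lab][1])
            ll = mk_loglik(tree, tips, model)
            assert ll == pytest.approx(
                brute_force_loglik(tree, tips, model), abs=1e-8
            )

    def test_traversal_order_invariance(self):
        """Relabeling children must not change the likelihood."""
        model = RateModel.dependent([0.3, 0.7, 0.2, 1.1, 0.4, 0.9, 0.5, 0.6])
        t1 = parse_newick("((A:1,B:2):1,(C:1,D:1):2);")
        t2 = parse_newick("((D:1,C:1):2,(B:2,A:1):1);")
        tips = {"A": (0, 1), "B": (1, 1), "C": (0, 0), "D": (1, 0)}
        assert mk_loglik(t1, tips, model) == pytest.approx(
            mk_loglik(t2, tips, model), abs=1e-12
        )

    def test_independent_model_factorizes(self):
        tree = simulate_tree(12, seed=4)
        model = RateModel.independent(0.4, 0.6, 1.2, 0.3)
        hist = simulate_characters(tree, model, seed=5)
        joint = mk_loglik(tree, hist.tip_states, model)
        la = mk_loglik(
            tree,
            {lab: (a, None) for lab, (a, b) in hist.tip_states.items()},
            model,
        )
        lb = mk_loglik(
            tree,
            {lab: (None, b) for lab, (a, b) in hist.tip_states.items()},
            model,
        )
        assert joint == pytest.approx(la + lb, abs=1e-10)

    def test_infinite_rate_rejected(self):
        with pytest.raises(ValidationError):
            RateModel.independent(float("inf"), 1, 1, 1)


class TestFit:
    def _data(self, n=40, seed=0):
        tree = simulate_tree(n, seed=seed)
        hist = simulate_characters(
            tree, RateModel.independent(0.3, 0.3, 0.3, 0.3), seed=seed + 1
        )
        return tree, hist.tip_states

    def test_deterministic_given_seed(self):
        tree, tips = self._data()
        f1 = fit(tree, tips, "dependent", n_starts=2, seed=42)
        f2 = fit(tree, tips, "dependent", n_starts=2, seed=42)
        assert f1.model.rates == f2.model.rates
        assert f1.loglik == f2.loglik

    def test_dependent_never_below_independent(self):
        for seed in range(8):
            tree, tips = self._data(n=25, seed=seed)
            fi = fit(tree, tips, "independent", n_starts=2, seed=seed)
            fd = fit(tree, tips, "dependent", n_starts=2, seed=seed)
            assert fd.loglik >= fi.loglik - 1e-6

    def test_nonvarying_character_rejected(self):
        tree = simulate_tree(10, seed=1)
        tips = {lab: (1, i % 2) for i, lab in enumerate(tree.tip_labels)}
        with pytest.raises(ValidationError, match="vary"):
            fit(tree, tips, "independent")


class TestPagelTest:
    def test_n_sim_floor(self):
        tree = simulate_tree(10, seed=1)
        tips = {lab: ((i % 2), ((i + 1) % 2)) for i, lab in enumerate(tree.tip_labels)}
        ta = {lab: s[0] for lab, s in tips.items()}
        tb = {lab: s[1] for lab, s in tips.items()}
        with pytest.raises(ValidationError, match="19"):
            pagel_test(tree, ta, tb, n_sim=5)

    def test_identical_traits_on_active_tree_detected(self):
        """A trait perfectly coupled to itself gives the minimal error percentage."""
        from pgtrait.synthetic_data import simulate_binary_history

        tree = simulate_tree(100, seed=3)
        hist = simulate_binary_history(tree, 0.25, 0.25, seed=4, root_state=1)
        ta = {lab: s[0] for lab, s in hist.tip_states.items()}
        assert len(hist.true_events) >= 10
        res = pagel_test(tree, ta, dict(ta), n_sim=19, seed=5)
        assert res.error_percentage <= 5.0
        assert res.score > 10.0

    def test_result_reports_inputs(self):
        tree = simulate_tree(30, seed=6)
        hist = simulate_characters(
            tree, RateModel.independent(0.3, 0.3, 0.3, 0.3), seed=7
        )
        ta = {lab: s[0] for lab, s in hist.tip_states.items()}
        tb = {lab: s[1] for lab, s in hist.tip_states.items()}
        res = pagel_test(tree, ta, tb, n_sim=19, seed=8)
        assert res.n_simulations == 19
        assert res.seed == 8
        assert res.score == pytest.approx(
            max(0.0, 2 * (res.loglik_dependent - res.loglik_independent))
        )
        assert 0 < res.error_percentage <= 100
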