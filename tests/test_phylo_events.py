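"""Newick handling, gain-penalizing parsimony, event extraction."""

import itertools

import numpy as np
import pytest

from pgtrait.annotation_io import Cohort, ValidationError
from pgtrait.phylo_events import (
    CostScheme,
    NewickError,
    ancestral_parsimony,
    character_from_cohort,
    extract_events,
    parse_newick,
    read_newick,
)
from pgtrait.synthetic_data import fixture_gt51_tree, simulate_tree

from conftest import make_record


def brute_force_min_cost(tree, tip_states, costs):
    """Exhaustive minimum over all internal-node assignments."""
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    fixed = {tree.tip_id_of[lab]: s for lab, s in tip_states.items()}
    best = float("inf")
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(fixed)
        cost = sum(
            costs.cost(st[tree.parent[v]], st[v])
            for v in range(tree.n_nodes)
            if v != tree.root
        )
        best = min(best, cost)
    return best


class TestNewick:
    def test_topology_counts(self):
        tree = parse_newick("((A,B),(C,D));")
        assert tree.n_tips == 4
        assert tree.n_nodes - tree.n_tips == 3

    def test_lengths_preserved(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        assert tree.n_tips == 4
        assert tree.has_branch_lengths()
        assert tree.lengths[tree.tip_id_of["A"]] == 1.0

    def test_roundtrip(self, tmp_path):
        tree = parse_newick("((A_1:1,B:2):0.5,(C:1,(D:1,E:1):1):1);")
        path = tmp_path / "t.nwk"
        tree.write_newick(path)
        back = read_newick(path)
        assert back.tip_labels == tree.tip_labels
        assert back.to_newick() == tree.to_newick()

    @pytest.mark.parametrize("bad", ["((A,B),(C,D);", "((A,B),(A,C));"])
    def test_parse_errors(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_polytomy_kept(self):
        tree = parse_newick("(A,B,C,(D,E));")
        root_children = tree.children[tree.root]
        assert len(root_children) == 4


class TestAncestralParsimony:
    def test_four_tip_worked_example(self):
        """Two 1-tips vs two 0-tips: one loss on the branch to the 0-clade."""
        tree = parse_newick("((A,B),(C,D));")
        a = ancestral_parsimony(
            tree, {"A": 1, "B": 1, "C": 0, "D": 0}, CostScheme(2.0, 1.0)
        )
        assert a.total_cost == 1.0
        assert a.states[tree.root] == 1
        events, counts = extract_events(a, tree)
        assert counts == {"gain": 0, "loss": 1}
        anc_cd = tree.parent[tree.tip_id_of["C"]]
        assert events[0].child_id == anc_cd

    def test_constant_tips_no_events(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        a = ancestral_parsimony(tree, dict.fromkeys("ABCDE", 1))
        assert a.total_cost == 0.0
        assert all(s == 1 for s in a.states)
        assert extract_events(a, tree)[0] == []

    def test_nested_gain_beats_multiple_losses(self):
        """One stem loss plus one regain (cost 3) beats four losses (cost 4)."""
        tree = parse_newick("(((((G,(A,B)),C),D),E),(O1,O2));")
        states = {"A": 1, "G": 0, "B": 0, "C": 0, "D": 0, "E": 0, "O1": 1, "O2": 1}
        a = ancestral_parsimony(tree, states, CostScheme(2.0, 1.0))
        assert a.total_cost == 3.0
        events, counts = extract_events(a, tree)
        assert counts == {"gain": 1, "loss": 1}
        gain = next(e for e in events if e.type == "gain")
        assert gain.child_id == tree.tip_id_of["A"]

    def test_missing_tip_named(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError, match="D"):
            ancestral_parsimony(tree, {"A": 1, "B": 1, "C": 0})

    def test_oracle_equivalence_random_trees(self):
        rng = np.random.default_rng(11)
        for case in range(100):
            tree = simulate_tree(int(rng.integers(3, 9)), seed=case)
            tips = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
            costs = CostScheme(float(rng.choice([1.0, 1.5, 2.0, 3.0])), 1.0)
            a = ancestral_parsimony(tree, tips, costs)
            assert a.total_cost == pytest.approx(
                brute_force_min_cost(tree, tips, costs)
            )

    def test_gain_count_monotone_in_gain_cost(self):
        rng = np.random.default_rng(3)
        for case in range(20):
            tree = simulate_tree(12, seed=100 + case)
            tips = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
            gains = []
            for g in (1.0, 1.5, 2.0, 3.0, 5.0):
                a = ancestral_parsimony(tree, tips, CostScheme(g, 1.0))
                _, counts = extract_events(a, tree)
                gains.append(counts["gain"])
            assert all(g1 >= g2 for g1, g2 in zip(gains, gains[1:]))

    def test_events_replay_to_tip_states(self):
        rng = np.random.default_rng(5)
        for case in range(20):
            tree = simulate_tree(15, seed=200 + case)
            tips = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
            a = ancestral_parsimony(tree, tips)
            events, _ = extract_events(a, tree)
            by_branch = {e.child_id: e for e in events}
            states = {tree.root: a.states[tree.root]}
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                s = states[tree.parent[v]]
                if v in by_branch:
                    s = 1 if by_branch[v].type == "gain" else 0
                states[v] = s
            for lab, tid in tree.tip_id_of.items():
                assert states[tid] == tips[lab]

    def test_equal_costs_match_fitch_parsimony(self):
        """With symmetric costs the minimum equals the Fitch change count."""
        from dendropy.model.parsimony import fitch_down_pass
        import dendropy

        rng = np.random.default_rng(8)
        for case in range(20):
            tree = simulate_tree(10, seed=300 + case)
            tips = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
            a = ancestral_parsimony(tree, tips, CostScheme(1.0, 1.0))
            # independent check with dendropy's Fitch implementation
            dtree = dendropy.Tree.get(
                data=tree.to_newick(), schema="newick", preserve_underscores=True
            )
            taxon_state_sets = {}
            for leaf in dtree.leaf_node_iter():
                leaf.state_sets = [set([tips[leaf.taxon.label]])]
            changes = fitch_down_pass(dtree.postorder_node_iter())
            assert a.total_cost == pytest.approx(changes)


class TestGT51FixtureTree:
    def test_reproduces_published_qualitative_history(self):
        tree, gt51, _ = fixture_gt51_tree()
        a = ancestral_parsimony(tree, gt51)
        _, counts = extract_events(a, tree)
        assert counts == {"gain": 1, "loss": 8}
        assert a.states[tree.root] == 1  # GT51-bearing bacterial ancestor

    def test_gain_is_akkermansia(self):
        tree, gt51, _ = fixture_gt51_tree()
        a = ancestral_parsimony(tree, gt51)
        events, _ = extract_events(a, tree)
        gain = next(e for e in events if e.type == "gain")
        assert tree.labels[gain.child_id] == "Akkermansia_muciniphila"

    def test_pg_loses_on_shared_branches(self):
        tree, gt51, pg_states = fixture_gt51_tree()
        ev_g, _ = extract_events(ancestral_parsimony(tree, gt51, character="GT51"), tree)
        ev_p, _ = extract_events(ancestral_parsimony(tree, pg_states, character="pg"), tree)
        shared = {e.child_id for e in ev_g if e.type == "loss"} & {
            e.child_id for e in ev_p if e.type == "loss"
        }
        assert len(shared) == 4


class TestCharacterFromCohort:
    def _cohort_tree(self):
        tree = parse_newick("((micromonas_like,chlamydia_like),unknown_like);")
        return tree

    def test_family_presence(self, toy_cohort):
        tree = self._cohort_tree()
        char = character_from_cohort(toy_cohort, "GT51", tree)
        assert char.states == {
            "micromonas_like": 1,
            "chlamydia_like": 0,
            "unknown_like": 1,
        }

    def test_set_presence(self, toy_cohort):
        tree = self._cohort_tree()
        char = character_from_cohort(toy_cohort, "set", tree)
        assert char.states["micromonas_like"] == 1
        assert char.states["chlamydia_like"] == 0

    def test_pg_excludes_unknown(self, toy_cohort):
        tree = self._cohort_tree()
        char = character_from_cohort(toy_cohort, "pg", tree)
        assert char.excluded_tips == ["unknown_like"]
        assert "unknown_like" not in char.states
        pruned = tree.prune_to([t for t in tree.tip_labels if t != "unknown_like"])
        assert pruned.n_tips == 2

    def test_missing_tip_listed(self, toy_cohort):
        tree = parse_newick("((micromonas_like,chlamydia_like),not_in_cohort);")
        with pytest.raises(ValidationError, match="not_in_cohort"):
            character_from_cohort(toy_cohort, "GT51", tree)
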