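"""Parsimony reconstruction against a brute-force oracle, policies, counts."""

import itertools
import random

import pytest

from matsys.synthetic_data import clade_fixture, simulate_history
from matsys.transition_inference import (
    STATES,
    PhyloTree,
    TreeError,
    count_switching_origins,
    count_transitions,
    enumerate_mprs,
    labeling_changes,
    labeling_gains_losses,
    parse_newick,
    parsimony_minimum,
    reconstruct_states,
)

# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------


def test_parse_simple_topology():
    tree = parse_newick("((A,B),C);")
    assert tree.n_tips == 3
    assert len(tree.root.child_nodes()) == 2


def test_branch_lengths_parsed_but_ignored():
    a = parse_newick("((A:1,B:2):0.5,C:3);")
    b = parse_newick("((A,B),C);")
    assert sorted(a.tip_names()) == sorted(b.tip_names())
    sa = count_transitions(reconstruct_states(a, {"A": "HET", "B": "PHC", "C": "HET"}))
    sb = count_transitions(reconstruct_states(b, {"A": "HET", "B": "PHC", "C": "HET"}))
    assert sa.counts == sb.counts


@pytest.mark.parametrize("bad", ["((A,B,C);", "(A,B)", "((A,B),A);", ""])
def test_malformed_newick_rejected(bad):
    with pytest.raises(TreeError):
        parse_newick(bad)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_minimum(tree, states, costs=None):
    """Exhaustive minimum over all ancestral labelings. With uniform costs
    the search can restrict to states observed at the tips (substituting an
    unobserved internal state with an observed neighbor never adds cost);
    with an arbitrary cost matrix an unobserved intermediate can be cheaper,
    so the full alphabet is searched."""
    observed = sorted(set(states.values())) if costs is None else list(STATES)
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    tip_state = {
        n.index: states[n.taxon.label] for n in tree.postorder() if n.is_leaf()
    }

    def cost(a, b):
        if costs is not None:
            return costs[(a, b)]
        return 0 if a == b else 1

    best = float("inf")
    for combo in itertools.product(observed, repeat=len(internals)):
        lab = dict(tip_state)
        for node, s in zip(internals, combo):
            lab[node.index] = s
        total = 0
        for node in tree.preorder():
            for child in node.child_nodes():
                total += cost(lab[node.index], lab[child.index])
        best = min(best, total)
    return best


def random_tree(rng, n_tips):
    names = [f"t{i}" for i in range(n_tips)]
    nodes = list(names)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b})")
    return parse_newick(nodes[0] + ";")


def test_fitch_minimum_matches_brute_force_on_50_random_instances():
    rng = random.Random(42)
    for _ in range(50):
        n = rng.randint(3, 7)
        tree = random_tree(rng, n)
        alphabet = rng.sample(STATES, rng.randint(2, 4))
        states = {name: rng.choice(alphabet) for name in tree.tip_names()}
        expected = brute_force_minimum(tree, states)
        assert parsimony_minimum(tree, states) == expected
        # policy containment: both policies resolve to an MPR
        for policy in ("default", "prefer_gains"):
            rec = reconstruct_states(tree, states, policy=policy)
            assert rec.n_changes == expected
            for node in tree.postorder():
                assert rec.resolved[node.index] in rec.candidate_states[node.index]


def test_sankoff_with_costs_matches_brute_force():
    rng = random.Random(7)
    for _ in range(10):
        tree = random_tree(rng, rng.randint(3, 6))
        alphabet = rng.sample(STATES, 3)
        states = {name: rng.choice(alphabet) for name in tree.tip_names()}
        costs = {
            (a, b): (0.0 if a == b else rng.choice([1.0, 2.0, 5.0]))
            for a in STATES
            for b in STATES
        }
        rec = reconstruct_states(tree, states, costs=costs)
        total = sum(
            costs[(rec.resolved[n.index], rec.resolved[c.index])]
            for n in tree.preorder()
            for c in n.child_nodes()
        )
        assert total == brute_force_minimum(tree, states, costs=costs)


def test_uniform_tips_reconstruct_with_zero_changes():
    tree = parse_newick("((A,B),(C,D));")
    states = {t: "HET" for t in "ABCD"}
    rec = reconstruct_states(tree, states)
    assert rec.n_changes == 0
    assert set(rec.resolved.values()) == {"HET"}
    assert len(enumerate_mprs(tree, states)) == 1
    assert count_transitions(rec).n_events == 0


def test_tip_permutation_invariance():
    states = {"A": "HET", "B": "FF1", "C": "FF1", "D": "PHC"}
    t1 = parse_newick("((A,B),(C,D));")
    t2 = parse_newick("((B,A),(D,C));")
    s1 = count_transitions(reconstruct_states(t1, states))
    s2 = count_transitions(reconstruct_states(t2, states))
    assert s1.counts == s2.counts


def test_missing_tip_policies():
    tree = parse_newick("((A,B),C);")
    states = {"A": "HET", "B": "HET"}
    with pytest.raises(TreeError):
        reconstruct_states(tree, states)
    rec = reconstruct_states(tree, states, missing="uninformative")
    assert rec.n_changes == 0


# ---------------------------------------------------------------------------
# MPR enumeration and prefer_gains
# ---------------------------------------------------------------------------


def test_every_enumerated_mpr_attains_the_minimum():
    rng = random.Random(99)
    for _ in range(20):
        tree = random_tree(rng, rng.randint(3, 7))
        alphabet = rng.sample(STATES, 3)
        states = {name: rng.choice(alphabet) for name in tree.tip_names()}
        mn = parsimony_minimum(tree, states)
        mprs = enumerate_mprs(tree, states)
        assert mprs
        assert all(labeling_changes(tree, lab) == mn for lab in mprs)
        assert len({tuple(sorted(l.items())) for l in mprs}) == len(mprs)


def test_enumeration_guard_on_large_trees():
    fx = clade_fixture("saccharomycetaceae")
    with pytest.raises(TreeError, match="max_tips"):
        enumerate_mprs(fx.tree, fx.states)


def test_prefer_gains_never_fewer_gains_than_any_mpr():
    rng = random.Random(5)
    for _ in range(20):
        tree = random_tree(rng, rng.randint(3, 7))
        alphabet = ["HET"] + rng.sample(
            [s for s in STATES if s != "HET"], 2
        )
        states = {name: rng.choice(alphabet) for name in tree.tip_names()}
        rec = reconstruct_states(tree, states, policy="prefer_gains")
        got_gains, _ = labeling_gains_losses(tree, rec.resolved)
        best = max(
            labeling_gains_losses(tree, lab)[0]
            for lab in enumerate_mprs(tree, states)
        )
        assert got_gains == best


# ---------------------------------------------------------------------------
# Transition counting and history round-trips
# ---------------------------------------------------------------------------


def test_switching_origin_definition():
    tree = parse_newick("((A,B),(C,D));")
    states = {"A": "FF1", "B": "HET", "C": "3LOC", "D": "HET"}
    rec = reconstruct_states(tree, states)
    summary = count_transitions(rec)
    assert count_switching_origins(summary) == 2  # HET->FF1 and HET->3LOC


def test_simulated_history_counts_recovered():
    tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    # two independent HET->PHN events on disjoint subtrees
    hist = simulate_history(
        tree,
        "HET",
        planted_events=[("A", "HET", "PHN"), ("G", "HET", "PHN")],
    )
    assert hist.tip_states == {
        "A": "PHN", "B": "HET", "C": "HET", "D": "HET",
        "E": "HET", "F": "HET", "G": "PHN", "H": "HET",
    }
    rec = reconstruct_states(tree, hist.tip_states)
    summary = count_transitions(rec)
    assert summary.counts == {("HET", "PHN"): 2}


def test_random_consistent_histories_recovered():
    tree = parse_newick("((((A,B),C),(D,(E,F))),((G,H),(I,(J,K))));")
    for seed in range(10):
        hist = simulate_history(
            tree, "HET", change_prob=0.15, seed=seed, require_consistent=True
        )
        rec = reconstruct_states(tree, hist.tip_states)
        assert rec.n_changes == len(hist.events)


def test_homoplastic_plant_rejected():
    tree = parse_newick("((A,B),(C,D));")
    # two sibling gains that parsimony would merge into one ancestral gain
    with pytest.raises(ValueError, match="homoplastic"):
        simulate_history(
            tree,
            "HET",
            planted_events=[
                ("A", "HET", "FF1"), ("B", "HET", "FF1"),
                ("C", "HET", "FF1"), ("D", "HET", "FF1"),
            ],
        )


def test_event_on_missing_branch_rejected():
    tree = parse_newick("((A,B),C);")
    with pytest.raises(ValueError, match="nonexistent"):
        simulate_history(tree, "HET", planted_events=[("Z", "HET", "FF1")])


def test_state_tree_serialization_labels_every_node():
    tree = parse_newick("((A,B),C);")
    rec = reconstruct_states(tree, {"A": "HET", "B": "HET", "C": "PHC"})
    text = rec.to_newick()
    assert text.endswith(";")
    assert "state=HET" in text and text.count("(") == 2
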