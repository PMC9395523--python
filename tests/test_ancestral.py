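"""F81 ancestral reconstruction against exhaustive enumeration."""

import numpy as np
import pytest

from cladecompare import (
    AncestralTraitModel,
    F81Model,
    f81_transition,
    fit_frequencies,
    marginal_posteriors,
    mppa_select,
    prune_likelihood,
)
from cladecompare.ancestral import AncestralError, empirical_frequencies

from oracles import enumerate_likelihood, random_enum_tree

STATES3 = ("coccoid", "muldi", "rod")


def test_transition_identity_at_zero():
    model = F81Model(("a", "b", "c"), (0.2, 0.3, 0.5))
    assert np.allclose(f81_transition(0.0, model), np.eye(3))


def test_transition_stationary_at_large_time():
    pi = (0.2, 0.3, 0.5)
    model = F81Model(("a", "b", "c"), pi)
    P = f81_transition(500.0, model)
    assert np.allclose(P, np.tile(pi, (3, 1)), atol=1e-12)


def test_transition_closed_form_value():
    model = F81Model(("a", "b"), (0.5, 0.5))
    assert model.beta == pytest.approx(2.0)
    P = f81_transition(0.5, model)
    expected = np.exp(-1.0) + (1 - np.exp(-1.0)) * 0.5
    assert P[0, 0] == pytest.approx(expected, rel=1e-12)
    assert np.allclose(P.sum(axis=1), 1.0)


def test_negative_branch_rejected():
    model = F81Model(("a", "b"), (0.5, 0.5))
    with pytest.raises(AncestralError):
        f81_transition(-0.1, model)


def test_single_leaf_likelihood_is_log_pi():
    model = F81Model(("a", "b"), (0.3, 0.7))
    assert prune_likelihood("t1:0.5;", {"t1": "b"}, model) == pytest.approx(
        np.log(0.7)
    )


def test_zero_length_discordant_cherry_is_impossible():
    model = F81Model(("a", "b"), (0.5, 0.5))
    ll = prune_likelihood("(t1:0.0,t2:0.0):0.0;", {"t1": "a", "t2": "b"}, model)
    assert ll == -np.inf


def test_unknown_state_rejected():
    model = F81Model(("a", "b"), (0.5, 0.5))
    with pytest.raises(AncestralError):
        prune_likelihood("(t1:0.1,t2:0.1):0.0;", {"t1": "a", "t2": "z"}, model)


@pytest.mark.parametrize("seed", range(6))
def test_likelihood_and_posteriors_match_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(3, 7))
    tree = random_enum_tree(n_leaves, rng)
    pi = rng.dirichlet(np.ones(3) * 4)
    model = F81Model(STATES3, tuple(pi))
    traits = {
        leaf.name: STATES3[int(rng.integers(0, 3))] for leaf in tree.leaves()
    }
    total, marginals = enumerate_likelihood(tree, traits, STATES3, pi)
    ll = prune_likelihood(tree.newick(), traits, model)
    assert ll == pytest.approx(np.log(total), abs=1e-9)
    post = marginal_posteriors(tree.newick(), traits, model)
    # preorder node order matches the enumeration tree's preorder
    for i, row in enumerate(post.itertuples(index=False)):
        assert np.allclose(np.array(row), marginals[i], atol=1e-9)


def test_symmetric_cherry_has_half_half_root_posterior():
    model = F81Model(("a", "b"), (0.5, 0.5))
    post = marginal_posteriors(
        "(t1:0.3,t2:0.3):0.0;", {"t1": "a", "t2": "b"}, model
    )
    root = post.iloc[0].to_numpy()
    assert np.allclose(root, [0.5, 0.5], atol=1e-12)


def test_zero_length_leaf_branch_pins_posterior():
    model = F81Model(("a", "b"), (0.4, 0.6))
    post = marginal_posteriors(
        "(t1:0.0,t2:0.7):0.0;", {"t1": "a", "t2": "b"}, model
    )
    assert np.allclose(post.loc["t1"].to_numpy(), [1.0, 0.0], atol=1e-12)


def test_posteriors_normalise_everywhere():
    rng = np.random.default_rng(10)
    tree = random_enum_tree(6, rng)
    model = F81Model(STATES3, (0.25, 0.25, 0.5))
    traits = {l.name: STATES3[int(rng.integers(0, 3))] for l in tree.leaves()}
    post = marginal_posteriors(tree.newick(), traits, model)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_mppa_worked_selections():
    import pandas as pd

    post = pd.DataFrame(
        [[1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.9, 0.1, 0.0]],
        index=["n1", "n2", "n3"], columns=["s1", "s2", "s3"],
    )
    sel = mppa_select(post)
    assert sel["n1"] == ("s1",)
    assert sel["n2"] == ("s1", "s2")
    assert sel["n3"] == ("s1",)


def test_fit_frequencies_symmetric_four_leaf_tree():
    newick = "((t1:0.2,t2:0.2):0.2,(t3:0.2,t4:0.2):0.2):0.0;"
    traits = {"t1": "a", "t2": "a", "t3": "b", "t4": "b"}
    model = fit_frequencies(newick, traits, ("a", "b"))
    assert model.pi[0] == pytest.approx(0.5, abs=1e-3)


def test_fit_frequencies_recovers_generating_pi():
    # simulate traits under F81 down a 200-leaf tree, then re-estimate
    rng = np.random.default_rng(123)
    from oracles import f81_matrix, random_enum_tree

    tree = random_enum_tree(200, rng)
    pi_true = np.array([0.6, 0.3, 0.1])

    def simulate(node, state):
        for child in node.children:
            P = f81_matrix(child.length, pi_true)
            child_state = int(rng.choice(3, p=P[state]))
            if child.children:
                simulate(child, child_state)
            else:
                traits[child.name] = STATES3[child_state]

    traits = {}
    root_state = int(rng.choice(3, p=pi_true))
    if not tree.children:
        traits[tree.name] = STATES3[root_state]
    simulate(tree, root_state)
    model = fit_frequencies(tree.newick(), traits, STATES3)
    assert np.allclose(model.pi, pi_true, atol=0.1)


def test_model_results_surface(small_clade):
    model = AncestralTraitModel(
        small_clade.truth.tree_newick, small_clade.truth.trait_map
    )
    res = model.fit(frequencies="empirical")
    assert res.posteriors.shape[1] == 2
    assert set(res.mppa) == set(res.posteriors.index)
    assert "MPPA" in res.summary()
    assert "mppa" in res.annotated_newick()
    # leaf posteriors are indicators
    for leaf, state in small_clade.truth.trait_map.items():
        assert res.posteriors.loc[leaf, state] == pytest.approx(1.0)


def test_empirical_frequencies_floor_unobserved():
    model = empirical_frequencies({"t1": "a", "t2": "a"}, ("a", "b"))
    assert model.pi[1] == pytest.approx(1e-6, rel=1e-3)  # floored, renormalised
    assert sum(model.pi) == pytest.approx(1.0)
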