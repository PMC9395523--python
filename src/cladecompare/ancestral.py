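"""Ancestral reconstruction of a discrete morphology trait.

Maximum-likelihood marginal reconstruction on a rooted tree under the F81
model, with MPPA (marginal posterior probabilities approximation) state
selection: at each node the prefix of posterior-descending states that
minimises the Brier distance to the posterior is reported, so ambiguous
nodes keep multi-state sets instead of being forced to a single call.

F81 over a state set S with equilibrium frequencies pi has the closed
form

    P(i -> j | t) = exp(-beta t) * delta_ij + (1 - exp(-beta t)) * pi_j,
    beta = 1 / (1 - sum_i pi_i^2),

so branch lengths are in expected-substitutions units.  Likelihoods come
from Felsenstein pruning; marginal posteriors from the standard up-down
(inside-outside) pass.  The modelling surface follows the Model/Results
convention (:class:`AncestralTraitModel` -> ``fit()`` ->
:class:`AncestralTraitResults`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

FREQ_FLOOR = 1e-6


class AncestralError(ValueError):
    """Invalid tree, trait or model input."""


@dataclass(frozen=True)
class F81Model:
    """F81 substitution model over an ordered discrete state set."""

    states: tuple[str, ...]
    pi: tuple[float, ...]

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if len(self.states) != pi.size or pi.size < 2:
            raise AncestralError("need >= 2 states with one frequency each")
        if (pi <= 0).any():
            raise AncestralError("equilibrium frequencies must be > 0")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise AncestralError("equilibrium frequencies must sum to 1")

    @property
    def beta(self) -> float:
        pi = np.asarray(self.pi)
        return 1.0 / (1.0 - float(pi @ pi))

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise AncestralError(
                f"state {state!r} not in state set {self.states}"
            ) from None


def f81_transition(t: float, model: F81Model) -> np.ndarray:
    """Transition probability matrix P(i -> j | t); rows sum to 1."""
    if t < 0:
        raise AncestralError(f"negative branch length {t}")
    pi = np.asarray(model.pi)
    decay = np.exp(-model.beta * t)
    return decay * np.eye(len(pi)) + (1.0 - decay) * np.tile(pi, (len(pi), 1))


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if not text.rstrip().endswith(";"):  # a path, not newick
        with open(text) as fh:
            text = fh.read()
    return dendropy.Tree.get(data=text, schema="newick")


def _prepare(tree: dendropy.Tree):
    """Label internal nodes deterministically and collect leaves."""
    leaves = []
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise AncestralError("unlabelled leaf in tree")
            node.node_id = node.taxon.label
            leaves.append(node.node_id)
        else:
            node.node_id = node.label or f"node{counter}"
            counter += 1
    if len(set(leaves)) != len(leaves):
        raise AncestralError("leaf names are not unique")
    return leaves


def _leaf_partial(state: str | None, model: F81Model) -> np.ndarray:
    k = len(model.states)
    if state is None:
        return np.ones(k)
    vec = np.zeros(k)
    vec[model.index(state)] = 1.0
    return vec


def _inside_pass(tree, traits, model):
    """Felsenstein pruning; stores scaled partials and log-scalers on nodes."""
    loglik_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.inside = _leaf_partial(traits.get(node.node_id), model)
        else:
            partial = np.ones(len(model.states))
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                P = f81_transition(t, model)
                partial = partial * (P @ child.inside)
            node.inside = partial
        scale = node.inside.max()
        if scale > 0:
            node.inside = node.inside / scale
            loglik_scale += np.log(scale)
        node.inside_logscale = loglik_scale  # cumulative is enough at root
    return loglik_scale


def prune_likelihood(tree, traits: dict[str, str], model: F81Model) -> float:
    """Log-likelihood of leaf states under F81 with the pi root prior.

    Missing leaves are allowed (all-ones partials).  Impossible data
    (zero likelihood, e.g. discordant tips joined by zero-length
    branches) returns ``-inf``.
    """
    tree = _load_tree(tree)
    leaves = _prepare(tree)
    unknown = set(traits) - set(leaves)
    if unknown:
        raise AncestralError(f"trait map names unknown leaves: {sorted(unknown)}")
    logscale = _inside_pass(tree, traits, model)
    root = tree.seed_node
    lik = float(np.asarray(model.pi) @ root.inside)
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logscale


def marginal_posteriors(
    tree, traits: dict[str, str], model: F81Model
) -> pd.DataFrame:
    """Marginal posterior state probabilities at every node.

    Up-down algorithm: the posterior at node v is proportional to
    inside(v) * outside(v); at the root, outside is the pi prior.
    Returns a frame indexed by node id (leaf names; internal nodes in
    preorder as node0, node1, ... with node0 the root) with one column
    per state, each row summing to 1.
    """
    tree = _load_tree(tree)
    leaves = _prepare(tree)
    unknown = set(traits) - set(leaves)
    if unknown:
        raise AncestralError(f"trait map names unknown leaves: {sorted(unknown)}")
    _inside_pass(tree, traits, model)
    root = tree.seed_node
    if float(np.asarray(model.pi) @ root.inside) <= 0.0:
        raise AncestralError("data have zero likelihood under the model")
    root.outside = np.asarray(model.pi, dtype=float)
    rows = {}
    order = []
    for node in tree.preorder_node_iter():
        if node is not root:
            parent = node.parent_node
            # outside(v) = P(t)^T @ [ outside(parent) * prod_{siblings} P@inside ]
            acc = parent.outside.copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                P_sib = f81_transition(sib.edge.length or 0.0, model)
                acc = acc * (P_sib @ sib.inside)
            P = f81_transition(node.edge.length or 0.0, model)
            node.outside = P.T @ acc
            s = node.outside.max()
            if s > 0:
                node.outside = node.outside / s
        post = node.inside * node.outside
        total = post.sum()
        if total <= 0:
            raise AncestralError(
                f"zero posterior mass at node {node.node_id}"
            )
        rows[node.node_id] = post / total
        order.append(node.node_id)
    return pd.DataFrame.from_dict(rows, orient="index", columns=model.states).loc[order]


def mppa_select(posteriors: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """MPPA state sets: the Brier-optimal prefix of each node's posterior.

    Among the prefixes of the posterior-descending state order, select
    the subset S* minimising sum_i (p_i - e_i)^2 with e_i = 1/|S*| inside
    the subset and 0 outside; ties go to the smaller subset.
    """
    states = list(posteriors.columns)
    selection = {}
    for node_id, row in posteriors.iterrows():
        p = row.to_numpy(dtype=float)
        order = np.argsort(-p, kind="mergesort")
        best_k, best_brier = 1, np.inf
        for k in range(1, len(states) + 1):
            e = np.zeros(len(states))
            e[order[:k]] = 1.0 / k
            brier = float(((p - e) ** 2).sum())
            if brier < best_brier - 1e-15:
                best_brier = brier
                best_k = k
        selection[node_id] = tuple(states[i] for i in order[:best_k])
    return selection


def empirical_frequencies(
    traits: dict[str, str], states: tuple[str, ...]
) -> F81Model:
    """F81 model with pi set to leaf-state proportions (floored)."""
    counts = np.array([sum(1 for v in traits.values() if v == s) for s in states],
                      dtype=float)
    pi = np.maximum(counts / counts.sum(), FREQ_FLOOR)
    pi = pi / pi.sum()
    return F81Model(states=tuple(states), pi=tuple(pi))


def fit_frequencies(
    tree, traits: dict[str, str], states: tuple[str, ...] | None = None
) -> F81Model:
    """Maximum-likelihood equilibrium frequencies under F81.

    The simplex is parameterised by softmax coordinates and optimised by
    Nelder-Mead from the empirical leaf proportions; frequencies of
    never-observed states are floored at 1e-6 and renormalised.
    """
    if states is None:
        states = tuple(sorted(set(traits.values())))
    if len(states) < 2:
        raise AncestralError("need at least two states to fit frequencies")
    tree = _load_tree(tree)

    def pi_of(theta: np.ndarray) -> np.ndarray:
        z = np.concatenate([[0.0], theta])
        z = z - z.max()
        pi = np.exp(z)
        pi = np.maximum(pi / pi.sum(), FREQ_FLOOR)
        return pi / pi.sum()

    def negloglik(theta: np.ndarray) -> float:
        model = F81Model(states=states, pi=tuple(pi_of(theta)))
        ll = prune_likelihood(tree, traits, model)
        return np.inf if ll == -np.inf else -ll

    start_model = empirical_frequencies(traits, states)
    start_pi = np.asarray(start_model.pi)
    theta0 = np.log(start_pi[1:]) - np.log(start_pi[0])
    result = optimize.minimize(
        negloglik, theta0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000},
    )
    return F81Model(states=states, pi=tuple(pi_of(result.x)))


class AncestralTraitModel:
    """Discrete-trait ancestral reconstruction model (F81 + MPPA).

    Parameters
    ----------
    tree : newick string, path, or dendropy.Tree
        Rooted tree with branch lengths.
    trait_map : mapping
        Leaf name -> observed state (e.g. rod / coccoid / muldi).
    states : tuple of str, optional
        Ordered state set; defaults to the sorted observed states.
    """

    def __init__(self, tree, trait_map: dict[str, str], states=None) -> None:
        self.tree = _load_tree(tree)
        self.trait_map = dict(trait_map)
        self.states = tuple(states) if states else tuple(
            sorted(set(self.trait_map.values()))
        )
        leaves = {
            leaf.taxon.label for leaf in self.tree.leaf_node_iter() if leaf.taxon
        }
        missing = leaves - set(self.trait_map)
        if missing:
            raise AncestralError(
                f"leaves without a trait assignment: {sorted(missing)[:5]} "
                "(pass them explicitly as None-free maps or drop the leaves)"
            )

    @classmethod
    def from_files(cls, newick_path, traits_csv, **kwargs) -> "AncestralTraitModel":
        traits = pd.read_csv(traits_csv)
        mapping = dict(zip(traits.iloc[:, 0], traits.iloc[:, 1]))
        with open(newick_path) as fh:
            return cls(fh.read(), mapping, **kwargs)

    def fit(self, frequencies: str = "ml") -> "AncestralTraitResults":
        """Reconstruct ancestral states.

        ``frequencies``: "ml" optimises pi by maximum likelihood (the
        PastML-style default); "empirical" uses leaf-state proportions.
        """
        if frequencies == "ml":
            model = fit_frequencies(self.tree, self.trait_map, self.states)
        elif frequencies == "empirical":
            model = empirical_frequencies(self.trait_map, self.states)
        else:
            raise AncestralError(f"unknown frequencies mode {frequencies!r}")
        loglik = prune_likelihood(self.tree, self.trait_map, model)
        posteriors = marginal_posteriors(self.tree, self.trait_map, model)
        selection = mppa_select(posteriors)
        return AncestralTraitResults(
            model=self,
            substitution_model=model,
            log_likelihood=loglik,
            posteriors=posteriors,
            mppa=selection,
        )


@dataclass
class AncestralTraitResults:
    """Fitted reconstruction: posteriors, MPPA sets and diagnostics."""

    model: AncestralTraitModel
    substitution_model: F81Model
    log_likelihood: float
    posteriors: pd.DataFrame
    mppa: dict[str, tuple[str, ...]]

    @property
    def root_id(self) -> str:
        return self.model.tree.seed_node.node_id

    @property
    def root_states(self) -> tuple[str, ...]:
        return self.mppa[self.root_id]

    def annotated_newick(self) -> str:
        """Newick with MPPA sets as node comments."""
        tree = self.model.tree
        for node in tree.preorder_node_iter():
            sel = "|".join(self.mppa[node.node_id])
            node.annotations.add_new("mppa", sel)
        out = io.StringIO()
        tree.write(file=out, schema="newick", suppress_annotations=False)
        return out.getvalue()

    def summary(self) -> str:
        pi = ", ".join(
            f"{s}={p:.3f}"
            for s, p in zip(self.substitution_model.states, self.substitution_model.pi)
        )
        root_post = self.posteriors.loc[self.root_id]
        lines = [
            "Ancestral trait reconstruction (F81 + MPPA)",
            f"  states: {', '.join(self.substitution_model.states)}",
            f"  equilibrium frequencies: {pi}",
            f"  log-likelihood: {self.log_likelihood:.4f}",
            f"  root posterior: "
            + ", ".join(f"{s}={root_post[s]:.3f}" for s in root_post.index),
            f"  root MPPA set: {{{', '.join(self.root_states)}}}",
            f"  ambiguous internal nodes (multi-state MPPA): "
            f"{sum(1 for v in self.mppa.values() if len(v) > 1)}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        frame = self.posteriors.copy()
        frame["mppa"] = [
            "|".join(self.mppa[i]) for i in frame.index
        ]
        frame.to_csv(path, sep="\t", index_label="node")
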