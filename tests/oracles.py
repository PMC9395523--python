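"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (quadratic/exponential) and shares
no code with the package beyond scoring-parameter values.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")


def smith_waterman_score(a: str, b: str, matrix_name="BLOSUM62",
                         gap_open=11.0, gap_extend=1.0) -> float:
    """Gotoh local-alignment score; first gap residue costs gap_open,
    each further residue gap_extend (matching the package's convention)."""
    m = substitution_matrices.load(matrix_name)
    n1, n2 = len(a), len(b)
    H = np.zeros((n1 + 1, n2 + 1))
    E = np.full((n1 + 1, n2 + 1), NEG)  # gap in a (moving along b)
    F = np.full((n1 + 1, n2 + 1), NEG)  # gap in b (moving along a)
    best = 0.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + m[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def needleman_wunsch(a: str, b: str, matrix_name="BLOSUM62",
                     gap_open=11.0, gap_extend=1.0):
    """Global affine-gap alignment; returns (aligned_a, aligned_b, score)."""
    m = substitution_matrices.load(matrix_name)
    n1, n2 = len(a), len(b)
    H = np.full((n1 + 1, n2 + 1), NEG)
    E = np.full((n1 + 1, n2 + 1), NEG)
    F = np.full((n1 + 1, n2 + 1), NEG)
    H[0][0] = 0.0
    for j in range(1, n2 + 1):
        E[0][j] = -gap_open - (j - 1) * gap_extend
        H[0][j] = E[0][j]
    for i in range(1, n1 + 1):
        F[i][0] = -gap_open - (i - 1) * gap_extend
        H[i][0] = F[i][0]
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + m[a[i - 1], b[j - 1]], E[i][j], F[i][j])
    return float(H[n1][n2])


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by literal definition:
    q_(i) = min_{j >= i} p_(j) * m / j on the sorted values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = q
    return out


class EnumTree:
    """Tiny rooted tree for exhaustive likelihood computation."""

    def __init__(self, name=None, length=0.0, children=()):
        self.name = name
        self.length = length
        self.children = list(children)

    def nodes(self):
        yield self
        for c in self.children:
            yield from c.nodes()

    def leaves(self):
        return [n for n in self.nodes() if not n.children]

    def newick(self):
        return self._nwk() + ";"

    def _nwk(self):
        if not self.children:
            return f"{self.name}:{self.length}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length}"


def random_enum_tree(n_leaves: int, rng: np.random.Generator) -> EnumTree:
    """Random binary topology with uniform(0.05, 1.0) branch lengths."""
    nodes = [EnumTree(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = EnumTree(length=float(rng.uniform(0.05, 1.0)),
                          children=(left, right))
        nodes.append(parent)
    nodes[0].length = 0.0
    return nodes[0]


def f81_matrix(t: float, pi: np.ndarray) -> np.ndarray:
    beta = 1.0 / (1.0 - float(pi @ pi))
    decay = np.exp(-beta * t)
    k = len(pi)
    return decay * np.eye(k) + (1 - decay) * np.tile(pi, (k, 1))


def enumerate_likelihood(tree: EnumTree, traits: dict[str, str],
                         states: tuple[str, ...], pi: np.ndarray):
    """Exhaustive sum over all interior-state assignments.

    Returns (total likelihood, {node index in preorder: marginal vector}).
    """
    nodes = list(tree.nodes())
    k = len(states)
    total = 0.0
    marginals = {i: np.zeros(k) for i in range(len(nodes))}
    index = {id(n): i for i, n in enumerate(nodes)}

    free = []
    fixed = {}
    for n in nodes:
        if not n.children:
            fixed[id(n)] = states.index(traits[n.name])
        else:
            free.append(n)
    for assignment in itertools.product(range(k), repeat=len(free)):
        state_of = dict(fixed)
        for n, s in zip(free, assignment):
            state_of[id(n)] = s
        lik = pi[state_of[id(tree)]]
        for n in nodes:
            for c in n.children:
                P = f81_matrix(c.length, pi)
                lik *= P[state_of[id(n)], state_of[id(c)]]
        total += lik
        for n in nodes:
            marginals[index[id(n)]][state_of[id(n)]] += lik
    for i in marginals:
        marginals[i] = marginals[i] / total
    return total, marginals


def transitive_closure_clusters(nodes, edges):
    """Connected components by naive repeated merging."""
    clusters = {n: {n} for n in nodes}
    rep = {n: n for n in nodes}
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            ru, rv = rep[u], rep[v]
            if ru != rv:
                clusters[ru] |= clusters[rv]
                for n in clusters[rv]:
                    rep[n] = ru
                del clusters[rv]
                changed = True
    return sorted(frozenset(c) for c in clusters.values())
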