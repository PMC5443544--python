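"""Phylogenetic signal in multivariate trait data.

Two complementary statistics are implemented:

* the morphometric **tree length** — the minimized, branch-length-weighted
  sum of squared trait changes over the tree, obtained by squared-change
  parsimony (equivalently, maximum likelihood under Brownian motion).  A
  short observed tree relative to tip-label permutations evidences signal;
  p-values are one-sided with the +1 Monte-Carlo correction.

* the **multivariate K statistic** (the generalization of Blomberg's K to
  high-dimensional shape data): the ratio of observed among-tip variation
  to its phylogenetically expected counterpart, scaled so that data evolving
  exactly by Brownian motion on the tree have expectation 1.  Significance
  comes from tip randomizations, favourable draws being those >= observed.

Both operate on any n x p tip matrix: full tangent coordinates, leading PC
scores, or logCS as the p = 1 case.  Bare topologies default to unit branch
lengths; zero lengths are floored at 1e-8 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import LENGTH_FLOOR, Phylogeny
from .errors import MorphosignalError, ParameterError


@dataclass
class AncestralReconstruction:
    node_values: np.ndarray          # n_nodes x p, tips exactly as observed
    tree_length: float               # minimized sum of (squared change)/length
    tip_indices: list[int]
    units_note: str = "squared trait distance per unit branch length"


@dataclass
class SignalTestResult:
    statistic_name: str              # "tree_length" or "k_mult"
    observed: float
    null_draws: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class PhyloCovariance:
    C: np.ndarray                    # N x N shared root-to-tip branch lengths
    tip_order: list[str]


def _working_lengths(tree: Phylogeny) -> np.ndarray:
    lengths = tree.lengths(default=1.0, floor=LENGTH_FLOOR)
    raw = tree.edge_length[tree.parent >= 0]
    if np.any(np.isfinite(raw) & (raw < LENGTH_FLOOR)):
        warnings.warn(f"zero-length branches floored at {LENGTH_FLOOR}")
    return lengths


def _tip_rows(tree: Phylogeny, tip_values: np.ndarray,
              tip_labels: list[str] | None) -> dict[int, int]:
    """Map tree tip index -> row of the data matrix."""
    n = tree.n_tips
    if tip_values.shape[0] != n:
        raise MorphosignalError(
            f"tip_values has {tip_values.shape[0]} rows but tree has {n} tips"
        )
    if tip_labels is None:
        return {t: i for i, t in enumerate(tree.tip_indices)}
    row_of = {lab: i for i, lab in enumerate(tip_labels)}
    missing = [t for t in tree.tip_labels if t not in row_of]
    if missing:
        raise MorphosignalError(f"tip labels with no data row: {missing}")
    return {t: row_of[tree.labels[t]] for t in tree.tip_indices}


def scp_reconstruct(
    tip_values: np.ndarray,
    tree: Phylogeny,
    tip_labels: list[str] | None = None,
) -> AncestralReconstruction:
    """Squared-change-parsimony ancestral states and the tree length.

    Internal node values minimize sum over branches of
    ||x_child - x_parent||^2 / length.  Setting gradients to zero makes each
    internal node the branch-length-weighted average of its neighbours; the
    resulting sparse linear system is solved exactly, one trait dimension at
    a time (the objective separates by coordinate).
    """
    x = np.atleast_2d(np.asarray(tip_values, dtype=float))
    if x.shape[0] == 1 and np.asarray(tip_values).ndim == 1:
        x = x.T
    lengths = _working_lengths(tree)
    row_map = _tip_rows(tree, x, tip_labels)

    n_nodes = tree.n_nodes
    tips = tree.tip_indices
    internal = [i for i in range(n_nodes) if tree.children[i]]
    int_pos = {nd: i for i, nd in enumerate(internal)}
    p = x.shape[1]

    a = np.zeros((len(internal), len(internal)))
    b = np.zeros((len(internal), p))
    for child in range(n_nodes):
        par = tree.parent[child]
        if par < 0:
            continue
        w = 1.0 / lengths[child]
        pi = int_pos[par]
        a[pi, pi] += w
        if child in int_pos:
            ci = int_pos[child]
            a[ci, ci] += w
            a[pi, ci] -= w
            a[ci, pi] -= w
        else:
            b[pi] += w * x[row_map[child]]

    node_values = np.zeros((n_nodes, p))
    for t in tips:
        node_values[t] = x[row_map[t]]
    node_values[internal] = np.linalg.solve(a, b)

    mask = tree.parent >= 0
    diffs = node_values[mask] - node_values[tree.parent[mask]]
    tree_length = float(np.sum(diffs**2 / lengths[mask, None]))
    return AncestralReconstruction(
        node_values=node_values, tree_length=tree_length, tip_indices=tips
    )


def tip_quadratic_form(tree: Phylogeny) -> np.ndarray:
    """Matrix Q with tree_length(X) = trace(X^T Q X) for tip data X.

    Eliminating the internal nodes from the weighted graph Laplacian leaves
    the Schur complement on the tips; the minimized objective is then a
    quadratic form in the tip values, which makes permutation tests cheap.
    Rows/columns follow the tree's tip order.
    """
    lengths = _working_lengths(tree)
    n_nodes = tree.n_nodes
    lap = np.zeros((n_nodes, n_nodes))
    for child in range(n_nodes):
        par = tree.parent[child]
        if par < 0:
            continue
        w = 1.0 / lengths[child]
        lap[child, child] += w
        lap[par, par] += w
        lap[child, par] -= w
        lap[par, child] -= w
    tips = tree.tip_indices
    internal = [i for i in range(n_nodes) if tree.children[i]]
    ltt = lap[np.ix_(tips, tips)]
    lti = lap[np.ix_(tips, internal)]
    lii = lap[np.ix_(internal, internal)]
    return ltt - lti @ np.linalg.solve(lii, lti.T)


def tree_length(tip_values: np.ndarray, tree: Phylogeny,
                tip_labels: list[str] | None = None) -> float:
    """Minimized sum of squared changes per branch length (scalar shortcut)."""
    return scp_reconstruct(tip_values, tree, tip_labels).tree_length


def tree_length_permutation_test(
    tip_values: np.ndarray,
    tree: Phylogeny,
    n_perm: int = 10_000,
    seed: int | None = None,
    tip_labels: list[str] | None = None,
) -> SignalTestResult:
    """Permutation test of the tree-length statistic.

    The topology is held fixed while rows of ``tip_values`` are shuffled
    across tips; signal is evidenced by an observed length shorter than the
    permuted ones, so p = (# draws <= observed + 1)/(n_perm + 1).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    x = np.atleast_2d(np.asarray(tip_values, dtype=float))
    if x.shape[0] == 1 and np.asarray(tip_values).ndim == 1:
        x = x.T
    if x.shape[0] < 4:
        raise MorphosignalError("need at least 4 tips for a permutation test")
    row_map = _tip_rows(tree, x, tip_labels)
    ordered = x[[row_map[t] for t in tree.tip_indices]]

    q = tip_quadratic_form(tree)
    observed = float(np.sum(ordered * (q @ ordered)))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    n = ordered.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n)
        xp = ordered[perm]
        draws[i] = np.sum(xp * (q @ xp))
    p = (np.count_nonzero(draws <= observed + 1e-12 * max(observed, 1.0)) + 1) / (n_perm + 1)
    return SignalTestResult(
        statistic_name="tree_length",
        observed=observed,
        null_draws=draws,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion tip covariance: C_ij = shared root-to-MRCA path length."""
    lengths = _working_lengths(tree)
    tips = tree.tip_indices
    n = len(tips)
    # depth of every node, then C_ij = depth of MRCA(i, j)
    depth = np.zeros(tree.n_nodes)
    for nd in range(1, tree.n_nodes):
        depth[nd] = depth[tree.parent[nd]] + lengths[nd]
    # tip sets below each node (trees here are small; quadratic is fine)
    below: list[set[int]] = [set() for _ in range(tree.n_nodes)]
    for nd in tree.postorder():
        if not tree.children[nd]:
            below[nd].add(nd)
        else:
            for c in tree.children[nd]:
                below[nd] |= below[c]
    c = np.zeros((n, n))
    tip_pos = {t: i for i, t in enumerate(tips)}
    for i, t in enumerate(tips):
        c[i, i] = depth[t]
    for nd in range(tree.n_nodes):
        kids = tree.children[nd]
        for ai in range(len(kids)):
            for bi in range(ai + 1, len(kids)):
                for ta in below[kids[ai]]:
                    for tb in below[kids[bi]]:
                        c[tip_pos[ta], tip_pos[tb]] = depth[nd]
                        c[tip_pos[tb], tip_pos[ta]] = depth[nd]
    return PhyloCovariance(C=c, tip_order=[tree.labels[t] for t in tips])


def k_mult_statistic(tip_values: np.ndarray, c: np.ndarray) -> float:
    """The multivariate K statistic for tip data Y and BM covariance C.

    With the phylogenetic mean a = (1' C^-1 1)^-1 (1' C^-1 Y):

        K = [tr(E'E) / tr(E' C^-1 E)] / [(tr C - N / (1' C^-1 1)) / (N - 1)]

    where E = Y - 1a.  Equals 1 in expectation under Brownian motion, and is
    exactly 1 on a unit-branch star tree (C = I).
    """
    y = np.atleast_2d(np.asarray(tip_values, dtype=float))
    if y.shape[0] == 1 and np.asarray(tip_values).ndim == 1:
        y = y.T
    n = y.shape[0]
    if c.shape != (n, n):
        raise MorphosignalError(f"C is {c.shape} but data has {n} rows")
    try:
        cinv_y = np.linalg.solve(c, y)
        cinv_1 = np.linalg.solve(c, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise MorphosignalError(
            "singular phylogenetic covariance; floor zero branch lengths"
        ) from exc
    s1 = float(np.ones(n) @ cinv_1)
    a = (np.ones(n) @ cinv_y) / s1
    e = y - a
    num = float(np.sum(e**2))
    den = float(np.sum(e * np.linalg.solve(c, e)))
    expected = (float(np.trace(c)) - n / s1) / (n - 1)
    return (num / den) / expected


def k_mult(
    tip_values: np.ndarray,
    tree: Phylogeny,
    n_rand: int = 999,
    seed: int | None = None,
    tip_labels: list[str] | None = None,
) -> SignalTestResult:
    """Multivariate K with a tip-randomization test (favourable: >= observed)."""
    if n_rand < 1:
        raise ParameterError("n_rand must be >= 1")
    y = np.atleast_2d(np.asarray(tip_values, dtype=float))
    if y.shape[0] == 1 and np.asarray(tip_values).ndim == 1:
        y = y.T
    if y.shape[0] < 4:
        raise MorphosignalError("need at least 4 tips")
    row_map = _tip_rows(tree, y, tip_labels)
    ordered = y[[row_map[t] for t in tree.tip_indices]]
    c = phylo_covariance(tree).C

    observed = k_mult_statistic(ordered, c)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_rand)
    n = ordered.shape[0]
    for i in range(n_rand):
        draws[i] = k_mult_statistic(ordered[rng.permutation(n)], c)
    p = (np.count_nonzero(draws >= observed) + 1) / (n_rand + 1)
    return SignalTestResult(
        statistic_name="k_mult",
        observed=float(observed),
        null_draws=draws,
        p_value=float(p),
        n_permutations=n_rand,
        seed=seed,
    )


def phylomorphospace(
    scores: np.ndarray,
    tree: Phylogeny,
    tip_labels: list[str] | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]], list[str | None]]:
    """Node coordinates for drawing the phylogeny through an ordination.

    Internal nodes sit at their squared-change-parsimony reconstructions in
    score space (reconstruction commutes with the linear projection onto PC
    loadings).  Returns (node coordinates (n_nodes x m), parent-child edge
    list, node labels).
    """
    rec = scp_reconstruct(scores, tree, tip_labels)
    edges = [(int(tree.parent[i]), i) for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    return rec.node_values, edges, list(tree.labels)
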