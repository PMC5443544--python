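"""Allometry: the dependence of shape on size, and its removal.

The static (sample-level) test regresses tangent-space shape coordinates on
log centroid size.  Both sides are mean-centered first, which makes the
no-intercept ("through the origin") multivariate regression exact; the
strength of allometry is the percent of total shape variation carried by
the predicted values, and significance comes from permuting logCS across
specimens.

Evolutionary allometry respects phylogenetic non-independence by working on
Felsenstein's standardized independent contrasts of species means: shape
contrasts are regressed on size contrasts through the origin (contrasts
have zero expectation, so no centering), with significance from permuting
and sign-flipping the size contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .datatypes import LENGTH_FLOOR, Phylogeny
from .errors import MorphosignalError, ParameterError


@dataclass
class AllometryResult:
    beta: np.ndarray                 # 2k shape change per unit (centered) logCS
    percent_predicted: float         # % of total shape variation explained
    residuals: np.ndarray            # n x 2k size-corrected coordinates (centered)
    mean_vector: np.ndarray          # grand mean shape of the input rows
    p_value: float
    n_permutations: int
    seed: int | None
    null_draws: np.ndarray           # permutation distribution of percent_predicted


def _percent_and_beta(x: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    ss = float(s @ s)
    beta = (x.T @ s) / ss
    predicted = np.outer(s, beta)
    total = float(np.sum(x**2))
    return 100.0 * float(np.sum(predicted**2)) / total, beta


def regress_shape_on_size(
    tangent: np.ndarray,
    log_cs: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    center: bool = True,
) -> AllometryResult:
    """Multivariate regression of shape on logCS with a permutation test.

    p = (# permuted percents >= observed + 1) / (n_perm + 1).  ``center=False``
    gives the strict through-origin variant on the raw rows (rarely wanted:
    it conflates the mean shape with allometry).
    """
    x = np.asarray(tangent, dtype=float)
    s = np.asarray(log_cs, dtype=float)
    if x.ndim != 2 or s.ndim != 1 or len(s) != len(x):
        raise MorphosignalError("tangent must be n x 2k and log_cs length n")
    if len(x) < 3:
        raise MorphosignalError("need at least 3 specimens")
    if np.ptp(s) == 0.0:
        raise ParameterError("log centroid size is constant: degenerate predictor")

    mean = x.mean(axis=0)
    if center:
        xc = x - mean
        sc = s - s.mean()
    else:
        xc, sc = x, s
    observed, beta = _percent_and_beta(xc, sc)
    residuals = xc - np.outer(sc, beta)

    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for i in range(n_perm):
        draws[i] = _percent_and_beta(xc, rng.permutation(sc))[0]
    p = (np.count_nonzero(draws >= observed) + 1) / (n_perm + 1)
    return AllometryResult(
        beta=beta,
        percent_predicted=observed,
        residuals=residuals,
        mean_vector=mean,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        null_draws=draws,
    )


def size_correct(result: AllometryResult) -> np.ndarray:
    """Size-corrected coordinates: residuals re-centered on the mean shape.

    The output drops into any downstream PCA or signal test unchanged;
    regressing it on the same sizes explains (numerically) nothing, so the
    correction is idempotent.
    """
    return result.residuals + result.mean_vector


@dataclass
class ContrastSet:
    """Felsenstein's standardized independent contrasts for shape and size."""

    contrasts_shape: np.ndarray      # (n - 1) x 2k
    contrasts_size: np.ndarray       # (n - 1,)
    node_order: list[int]            # internal-node indices, postorder


def pic_matrix(values: np.ndarray, tree: Phylogeny,
               tip_labels: list[str] | None = None) -> tuple[np.ndarray, list[int]]:
    """Standardized contrasts of an n x p tip matrix; returns (contrasts, nodes).

    Post-order pruning: at each internal node with children carrying values
    x_i, x_j on (working) branch lengths l_i, l_j, the contrast is
    (x_i - x_j) / sqrt(l_i + l_j), the node inherits the branch-length-
    weighted average, and its own branch is extended by l_i l_j/(l_i + l_j).
    Polytomies are resolved into zero-length bifurcations first (with a
    warning); rows follow ``tip_labels`` or the tree's tip order.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[0] == 1 and x.shape[1] == tree.n_tips and values.ndim == 1:
        x = x.T
    if not tree.is_bifurcating():
        warnings.warn("resolving polytomies to zero-length bifurcations for PIC")
        tree = tree.resolve_polytomies()
    n = tree.n_tips
    if x.shape[0] != n:
        raise MorphosignalError(f"values have {x.shape[0]} rows but tree has {n} tips")

    labels = tip_labels if tip_labels is not None else tree.tip_labels
    row_of = {lab: i for i, lab in enumerate(labels)}
    missing = [t for t in tree.tip_labels if t not in row_of]
    if missing:
        raise MorphosignalError(f"tip labels with no data row: {missing}")

    lengths = tree.lengths()
    work_len = lengths.astype(float).copy()
    node_val: dict[int, np.ndarray] = {}
    for i in tree.tip_indices:
        node_val[i] = x[row_of[tree.labels[i]]]

    contrasts = []
    node_order = []
    for nd in tree.postorder():
        kids = tree.children[nd]
        if not kids:
            continue
        if len(kids) != 2:  # pragma: no cover - resolved above
            raise MorphosignalError("PIC requires a bifurcating tree")
        i, j = kids
        li = max(work_len[i], LENGTH_FLOOR)
        lj = max(work_len[j], LENGTH_FLOOR)
        contrasts.append((node_val[i] - node_val[j]) / np.sqrt(li + lj))
        node_val[nd] = (node_val[i] / li + node_val[j] / lj) / (1.0 / li + 1.0 / lj)
        work_len[nd] = work_len[nd] + li * lj / (li + lj)
        node_order.append(nd)
    return np.stack(contrasts), node_order


def pic_contrasts(
    shape_values: np.ndarray,
    size_values: np.ndarray,
    tree: Phylogeny,
    tip_labels: list[str] | None = None,
) -> ContrastSet:
    """Contrasts of species-mean shape and size on the same tree."""
    cs_shape, order = pic_matrix(shape_values, tree, tip_labels)
    cs_size, _ = pic_matrix(np.asarray(size_values, dtype=float).reshape(-1, 1),
                            tree, tip_labels)
    return ContrastSet(contrasts_shape=cs_shape,
                       contrasts_size=cs_size[:, 0],
                       node_order=order)


def evolutionary_allometry_test(
    contrasts: ContrastSet,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AllometryResult:
    """Allometry on independent contrasts, through the origin.

    The null distribution permutes the pairing of size contrasts with shape
    contrasts and flips their signs (contrasts are sign-arbitrary), giving
    p = (# >= observed + 1)/(n_perm + 1).
    """
    xc = np.asarray(contrasts.contrasts_shape, dtype=float)
    sc = np.asarray(contrasts.contrasts_size, dtype=float)
    if len(xc) < 2:
        raise MorphosignalError("need at least 2 contrasts (3 tips)")
    if np.all(sc == 0.0):
        raise ParameterError("all size contrasts are zero: degenerate predictor")
    observed, beta = _percent_and_beta(xc, sc)
    residuals = xc - np.outer(sc, beta)

    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=len(sc))
        draws[i] = _percent_and_beta(xc, signs * rng.permutation(sc))[0]
    p = (np.count_nonzero(draws >= observed) + 1) / (n_perm + 1)
    return AllometryResult(
        beta=beta,
        percent_predicted=observed,
        residuals=residuals,
        mean_vector=np.zeros(xc.shape[1]),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        null_draws=draws,
    )
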