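"""Synthetic landmark datasets with known evolutionary ground truth.

The generator mirrors the statistical structure the analysis assumes:
species mean shapes drift by multivariate Brownian motion on a phylogeny,
specimens scatter isotropically around their species mean, log centroid
size carries its own Brownian component plus specimen noise, and an
optional allometric vector couples shape to size.  Every emitted
configuration is pushed through a random similarity motion (rotation,
translation, digitizer scale) so the pipeline must genuinely superimpose;
the digitizer scale is recorded as the configuration's ``scale_factor`` so
the intended physical size is recoverable with ``scale_policy='apply'``.

One global seed feeds per-stage ``SeedSequence`` streams (tree, Brownian
motion, sizes, landmark noise, rigid motions), so any stage can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkConfiguration, LandmarkDataset, Phylogeny
from .errors import ParameterError
from .procrustes import centroid_size, similarity_directions

# An asymmetric, hook-like 8-landmark template (arbitrary units): a blunt
# root block, a curved shaft and a recurved point.  Any non-degenerate
# asymmetric template works; asymmetry keeps reflections detectable.
ANCHOR_TEMPLATE = np.array(
    [
        [0.00, 1.00],    # inner root tip
        [-0.55, 0.80],   # outer root tip
        [-0.25, 0.55],   # root junction
        [0.20, 0.45],    # shaft base
        [0.30, -0.10],   # shaft midpoint
        [0.15, -0.65],   # shaft/point flexure
        [-0.25, -0.95],  # point curve
        [-0.60, -0.75],  # point tip
    ]
)


@dataclass
class SyntheticConfig:
    """Everything that determines a synthetic dataset (given the seed)."""

    n_tips: int = 14
    k: int = 8
    bm_rate: float = 1e-3            # per-dimension Brownian rate for shape
    noise_sd: float = 5e-3           # within-species landmark coordinate sd
    n_specimens_per_species: int = 20
    allometry_beta: np.ndarray | None = None   # 2k vector, or None for zero
    beta_norm: float = 0.0           # used when allometry_beta is None
    size_mean: float = 0.0           # grand mean logCS
    size_bm_rate: float = 0.01       # Brownian rate of species logCS
    size_sd: float = 0.05            # within-species logCS sd
    anchor_side: str = "ventral"
    tree: Phylogeny | None = None    # supplied tree overrides n_tips
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bm_rate", "noise_sd", "size_bm_rate", "size_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.k < 3:
            raise ParameterError("k must be >= 3")


def _stage_rngs(seed: int, n: int = 5) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def random_tree(n_tips: int, rng: np.random.Generator | int | None = None,
                labels: list[str] | None = None) -> Phylogeny:
    """Random bifurcating rooted tree with Exponential(1) branch lengths.

    Topology grows by splitting a uniformly chosen tip (a Yule process up to
    relabelling), which gives realistic imbalance without committing to a
    particular diversification model.
    """
    if n_tips < 2:
        raise ParameterError("need at least 2 tips")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ParameterError("labels length must equal n_tips")

    parent = [-1, 0, 0]
    children: list[list[int]] = [[1, 2], [], []]
    tips = [1, 2]
    while len(tips) < n_tips:
        split = tips.pop(int(rng.integers(len(tips))))
        a, b = len(parent), len(parent) + 1
        parent.extend([split, split])
        children[split] = [a, b]
        children.extend([[], []])
        tips.extend([a, b])
    n_nodes = len(parent)
    edge = np.concatenate([[np.nan], rng.exponential(1.0, size=n_nodes - 1)])
    node_labels: list[str | None] = [None] * n_nodes
    shuffled = list(labels)
    rng.shuffle(shuffled)
    for lab, t in zip(shuffled, tips):
        node_labels[t] = lab
    tree = Phylogeny(
        parent=np.array(parent),
        children=children,
        edge_length=edge,
        labels=node_labels,
    )
    return tree._reindex_preorder()


def simulate_bm_tips(
    tree: Phylogeny,
    rate: float | np.ndarray,
    p: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Multivariate Brownian motion down the tree; returns tips x p values.

    The root sits at zero; each branch adds independent Gaussian increments
    with variance rate x branch length per dimension.  ``rate`` may be a
    scalar or a length-p vector of per-dimension rates.  Rows follow the
    tree's tip order.
    """
    rate_vec = np.broadcast_to(np.asarray(rate, dtype=float), (p,))
    if np.any(rate_vec < 0):
        raise ParameterError("Brownian rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = tree.lengths()
    values = np.zeros((tree.n_nodes, p))
    for nd in range(1, tree.n_nodes):  # preorder: parents precede children
        sd = np.sqrt(rate_vec * lengths[nd])
        values[nd] = values[tree.parent[nd]] + rng.normal(0.0, 1.0, size=p) * sd
    return values[tree.tip_indices]


def _tangent_basis_complement(base: np.ndarray) -> np.ndarray:
    """Projector onto the tangent space at the (unit-CS, centered) base shape."""
    k = base.shape[0]
    sims = similarity_directions(base)
    proj = np.eye(2 * k) - sims.T @ sims
    return proj


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[LandmarkDataset, Phylogeny, dict]:
    """Simulate a full landmark dataset plus its generating truth record.

    Species mean shapes are the anchor template plus Brownian deviations
    confined to the template's tangent space; specimen shapes add the
    allometric component beta x (logCS - species mean logCS) and isotropic
    landmark noise, are scaled to their intended centroid size exp(logCS),
    and finally receive a random rotation, translation and digitizer scale.
    """
    rng_tree, rng_bm, rng_size, rng_noise, rng_rigid = _stage_rngs(config.seed)

    if config.k != ANCHOR_TEMPLATE.shape[0]:
        # resample the template outline to k points on its polygon
        raise ParameterError("only k = 8 templates are built in; pass custom data "
                             "through the pipeline directly for other k")
    tree = config.tree if config.tree is not None else random_tree(
        config.n_tips, rng_tree)
    n_sp = tree.n_tips
    labels = tree.tip_labels
    k = config.k
    p = 2 * k

    base = ANCHOR_TEMPLATE - ANCHOR_TEMPLATE.mean(axis=0)
    base = base / centroid_size(base)
    proj = _tangent_basis_complement(base)

    beta = config.allometry_beta
    if beta is None:
        if config.beta_norm > 0:
            direction = proj @ rng_bm.normal(size=p)
            beta = config.beta_norm * direction / np.linalg.norm(direction)
        else:
            beta = np.zeros(p)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (p,):
        raise ParameterError(f"allometry_beta must have length {p}, got {beta.shape}")
    beta = proj @ beta  # keep the coupling inside shape space

    # species mean shapes: BM deviations projected into the tangent space
    deviations = simulate_bm_tips(tree, config.bm_rate, p, seed=rng_bm) @ proj.T
    species_means = base.reshape(-1) + deviations

    # species mean logCS: grand mean + BM component
    species_logcs = config.size_mean + simulate_bm_tips(
        tree, config.size_bm_rate, 1, seed=rng_size)[:, 0]

    configs: list[LandmarkConfiguration] = []
    truth_logcs: dict[str, float] = {}
    for s_idx, sp in enumerate(labels):
        for j in range(config.n_specimens_per_species):
            logcs = species_logcs[s_idx] + rng_size.normal(0.0, config.size_sd)
            vec = (
                species_means[s_idx]
                + beta * (logcs - species_logcs[s_idx])
                + config.noise_sd * rng_noise.normal(size=p)
            )
            coords = vec.reshape(k, 2)
            coords = coords - coords.mean(axis=0)
            cs = np.sqrt(np.sum(coords**2))
            if cs == 0.0:
                coords = base.copy()
                cs = 1.0
            coords = coords * (np.exp(logcs) / cs)  # physical units
            # random similarity motion: rotation, translation, digitizer scale
            theta = rng_rigid.uniform(0.0, 2.0 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            shift = rng_rigid.uniform(-2.0, 2.0, size=2)
            digitizer_scale = np.exp(rng_rigid.uniform(-0.5, 0.5))
            emitted = coords @ rot.T / digitizer_scale + shift
            specimen = f"{sp}_s{j + 1:02d}"
            truth_logcs[specimen] = float(logcs)
            configs.append(
                LandmarkConfiguration(
                    specimen_id=specimen,
                    species_id=sp,
                    anchor_side=config.anchor_side,
                    coords=emitted,
                    scale_factor=float(digitizer_scale),
                )
            )
    truth = {
        "seed": config.seed,
        "species_means": {sp: species_means[i].tolist() for i, sp in enumerate(labels)},
        "species_logcs": {sp: float(species_logcs[i]) for i, sp in enumerate(labels)},
        "specimen_logcs": truth_logcs,
        "beta": beta.tolist(),
        "bm_rate": config.bm_rate,
        "noise_sd": config.noise_sd,
        "size_bm_rate": config.size_bm_rate,
        "size_sd": config.size_sd,
        "base_shape": base.reshape(-1).tolist(),
    }
    return LandmarkDataset(configs), tree, truth


def null_scenario(
    dataset: LandmarkDataset,
    mode: str = "shuffle_species",
    seed: int | None = None,
) -> LandmarkDataset:
    """Remove any species-tree association from a dataset, labels only.

    ``shuffle_species`` permutes species names across the species groups
    (each species keeps its cohesive specimen set under a new name);
    ``iid_species`` permutes the specimen-to-species assignment across all
    specimens, so each species' sample becomes an i.i.d. draw from the pooled
    population and species means are independent of any tree.  Both modes
    preserve the multiset of configurations exactly.
    """
    rng = np.random.default_rng(seed)
    configs = dataset.configurations
    if mode == "shuffle_species":
        species = dataset.species()
        permuted = list(species)
        rng.shuffle(permuted)
        relabel = dict(zip(species, permuted))
        new = [
            LandmarkConfiguration(
                specimen_id=c.specimen_id,
                species_id=relabel[c.species_id],
                anchor_side=c.anchor_side,
                coords=c.coords.copy(),
                scale_factor=c.scale_factor,
            )
            for c in configs
        ]
        return LandmarkDataset(new)
    if mode == "iid_species":
        assignment = [c.species_id for c in configs]
        order = rng.permutation(len(assignment))
        new = [
            LandmarkConfiguration(
                specimen_id=c.specimen_id,
                species_id=assignment[order[i]],
                anchor_side=c.anchor_side,
                coords=c.coords.copy(),
                scale_factor=c.scale_factor,
            )
            for i, c in enumerate(configs)
        ]
        return LandmarkDataset(new)
    raise ParameterError(f"unknown null mode {mode!r}")
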