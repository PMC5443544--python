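"""Generalized Procrustes Analysis for 2-D landmark configurations.

Superimposition removes position (centering), scale (unit centroid size,
i.e. partial Procrustes) and orientation (proper rotation onto the running
consensus).  The fitted coordinates are finished with an orthogonal
projection onto the tangent space at the consensus, which leaves vectors
orthogonal to all four similarity directions (two translations, rotation,
scaling) so that ordinary multivariate statistics apply downstream.

Rotations are restricted to determinant +1 by default: left and right
anchors must never be mirrored silently.  ``allow_reflection=True`` permits
the full orthogonal group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkDataset
from .errors import ConvergenceError, DegenerateShapeError, MorphosignalError


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Homogeneous of degree 1 in the coordinates, so doubling every coordinate
    doubles CS.  Raises :class:`DegenerateShapeError` when all landmarks
    coincide (CS = 0, shape undefined).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 1:
        raise ValueError("config must be a k x d coordinate matrix")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise DegenerateShapeError("all landmarks coincident: centroid size is 0")
    return cs


def _center_and_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    cs = centroid_size(config)
    return centered / cs, cs


def optimal_rotation(
    target: np.ndarray, moving: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """Orthogonal matrix R minimizing ||moving @ R - target||_F.

    Solves the two-configuration Procrustes problem by SVD; when reflection
    is disallowed the smaller singular value's sign is flipped to force
    det(R) = +1.
    """
    m = moving.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection or d >= 0:
        return u @ vt
    flip = np.diag([1.0] * (m.shape[0] - 1) + [-1.0])
    return u @ flip @ vt


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = False
) -> float:
    """Partial Procrustes distance between two centered, unit-CS shapes.

    sqrt of the minimal summed squared coordinate difference over rotations
    of ``b`` onto ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise MorphosignalError(f"shape dimension mismatch: {a.shape} vs {b.shape}")
    for name, x in (("a", a), ("b", b)):
        if not np.allclose(x.mean(axis=0), 0.0, atol=1e-8):
            raise MorphosignalError(f"shape {name} is not centered")
        if not np.isclose(np.sqrt(np.sum(x**2)), 1.0, atol=1e-8):
            raise MorphosignalError(f"shape {name} does not have unit centroid size")
    r = optimal_rotation(a, b, allow_reflection=allow_reflection)
    return float(np.sqrt(max(0.0, np.sum((b @ r - a) ** 2))))


@dataclass
class AlignedDataset:
    """Output of GPA: superimposed coordinates plus size variables.

    ``consensus`` has unit centroid size; ``aligned`` holds the n fitted
    k x 2 configurations; ``tangent`` the same data as n x 2k row vectors
    after tangent projection.  ``centroid_size`` is measured on the input
    coordinates before any scaling (original units).
    """

    consensus: np.ndarray
    aligned: np.ndarray
    tangent: np.ndarray
    centroid_size: np.ndarray
    log_cs: np.ndarray
    specimen_ids: list[str] = field(default_factory=list)
    species_ids: list[str] = field(default_factory=list)
    anchor_side: str | None = None
    n_iterations: int = 0

    @property
    def n(self) -> int:
        return self.tangent.shape[0]

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    def species_means(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Per-species means of tangent coordinates and of logCS.

        Returns (species labels in first-appearance order, means n_species x 2k,
        mean logCS per species).
        """
        if not self.species_ids:
            raise MorphosignalError("dataset carries no species labels")
        order: list[str] = []
        for s in self.species_ids:
            if s not in order:
                order.append(s)
        idx = {s: i for i, s in enumerate(order)}
        groups = [[] for _ in order]
        for row, s in enumerate(self.species_ids):
            groups[idx[s]].append(row)
        means = np.stack([self.tangent[g].mean(axis=0) for g in groups])
        mean_logcs = np.array([self.log_cs[g].mean() for g in groups])
        return order, means, mean_logcs


def gpa(
    data: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
    scale_policy: str = "ignore",
) -> AlignedDataset:
    """Iterative Generalized Procrustes superimposition.

    Each configuration is centered and scaled to unit centroid size, then
    repeatedly rotated onto the running consensus (initialized from the
    first configuration); the consensus is the mean of the rotated
    configurations rescaled to unit CS.  Iteration stops when the
    root-mean-square consensus change drops below ``tol``.
    """
    if isinstance(data, LandmarkDataset):
        coords = data.coords_array(scale_policy)
        specimen_ids = data.specimen_ids
        species_ids = data.species_ids
        sides = set(data.sides)
        side = sides.pop() if len(sides) == 1 else None
    else:
        coords = np.asarray(data, dtype=float)
        specimen_ids, species_ids, side = [], [], None
    if coords.ndim != 3 or coords.shape[2] != 2:
        raise MorphosignalError("expected an n x k x 2 coordinate array")
    n = coords.shape[0]
    if n < 2:
        raise MorphosignalError("GPA needs at least 2 configurations")

    cs = np.empty(n)
    scaled = np.empty_like(coords)
    for i in range(n):
        scaled[i], cs[i] = _center_and_scale(coords[i])

    consensus = scaled[0].copy()
    aligned = scaled.copy()
    delta = np.inf
    for iteration in range(1, max_iter + 1):
        for i in range(n):
            r = optimal_rotation(consensus, scaled[i], allow_reflection)
            aligned[i] = scaled[i] @ r
        new_consensus = aligned.mean(axis=0)
        norm = np.sqrt(np.sum(new_consensus**2))
        if norm == 0.0:
            raise DegenerateShapeError("consensus collapsed to a point")
        new_consensus /= norm
        delta = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last RMS consensus change {delta:.3e})",
            last_delta=delta,
        )
    # canonical orientation: principal axes of the consensus on the
    # coordinate axes, with the largest-|.| consensus coordinate positive.
    # This makes the fit invariant to a common rotation of the inputs
    # (the consensus is otherwise only defined up to rotation).
    consensus = consensus @ _principal_axis_rotation(consensus)
    # final pass against the converged consensus
    for i in range(n):
        r = optimal_rotation(consensus, scaled[i], allow_reflection)
        aligned[i] = scaled[i] @ r

    tangent = _tangent_project(aligned, consensus)
    return AlignedDataset(
        consensus=consensus,
        aligned=aligned,
        tangent=tangent,
        centroid_size=cs,
        log_cs=np.log(cs),
        specimen_ids=list(specimen_ids),
        species_ids=list(species_ids),
        anchor_side=side,
        n_iterations=iteration,
    )


def _principal_axis_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to a deterministic orientation."""
    m = consensus.T @ consensus
    _, vecs = np.linalg.eigh(m)
    v = vecs[:, ::-1]  # major axis first
    if np.linalg.det(v) < 0:
        v[:, 1] = -v[:, 1]
    rotated = consensus @ v
    flat = rotated.reshape(-1)
    if flat[int(np.argmax(np.abs(flat)))] < 0:
        v = -v  # rotate by 180 degrees (still proper)
    return v


def _tangent_project(aligned: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection removing the component along the consensus.

    Rows of the result are 2k vectors orthogonal to the scaling direction
    (the consensus itself); centering and the rotation optimum already make
    them orthogonal to translations and to the rotation direction.
    """
    n, k, _ = aligned.shape
    c = consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    flat = aligned.reshape(n, 2 * k)
    return flat - np.outer(flat @ c, c)


def similarity_directions(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4 x 2k) of the similarity-transform directions.

    Rows: x-translation, y-translation, infinitesimal rotation, scaling —
    the directions tangent vectors must be orthogonal to.
    """
    k = consensus.shape[0]
    tx = np.zeros((k, 2))
    tx[:, 0] = 1.0
    ty = np.zeros((k, 2))
    ty[:, 1] = 1.0
    rot = np.column_stack([-consensus[:, 1], consensus[:, 0]])
    scale = consensus.copy()
    basis = np.stack([tx.reshape(-1), ty.reshape(-1), rot.reshape(-1), scale.reshape(-1)])
    # Gram-Schmidt (rotation/scaling are already orthogonal to translations
    # for a centered consensus, but orthonormalize defensively)
    q, _ = np.linalg.qr(basis.T)
    return q.T[: basis.shape[0]]
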