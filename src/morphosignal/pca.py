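"""PCA of tangent-space shape coordinates.

Performed on the sample covariance matrix (divisor n - 1) of the centered
input; superimposed 2-D data have at most 2k - 4 nonzero eigenvalues, and
the decomposition keeps every component so variance proportions always sum
to one.  Two levels are exposed: specimen (rows as given) and species_mean
(rows averaged within species before decomposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MorphosignalError, ValidationError


@dataclass
class ShapePCAResult:
    mean_vector: np.ndarray          # 2k grand mean of the analysed rows
    eigenvalues: np.ndarray          # descending, >= 0
    proportions: np.ndarray          # eigenvalues / sum
    scores: np.ndarray               # n x m, zero column means
    loadings: np.ndarray             # m x 2k, rows are unit eigenvectors
    level: str
    row_labels: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def cumulative_percent(self, top: int) -> float:
        return float(100.0 * self.proportions[:top].sum())


def shape_pca(
    tangent: np.ndarray,
    level: str = "specimen",
    species_ids: list[str] | None = None,
    row_labels: list[str] | None = None,
) -> ShapePCAResult:
    """Eigen-decompose the covariance of tangent coordinates.

    ``level='species_mean'`` first averages rows within species (labels in
    first-appearance order).  Loadings follow a deterministic sign
    convention: the largest-magnitude element of each eigenvector is made
    positive.
    """
    x = np.asarray(tangent, dtype=float)
    if x.ndim != 2:
        raise MorphosignalError("tangent must be an n x 2k matrix")
    labels = list(row_labels) if row_labels is not None else [str(i) for i in range(len(x))]

    if level == "species_mean":
        if species_ids is None:
            raise MorphosignalError("species_mean level requires species_ids")
        if len(species_ids) != len(x):
            raise MorphosignalError("species_ids length does not match rows")
        order: list[str] = []
        for s in species_ids:
            if s not in order:
                order.append(s)
        rows = []
        for s in order:
            members = [i for i, sp in enumerate(species_ids) if sp == s]
            if not members:
                raise ValidationError(f"species {s!r} has no specimens after filtering")
            rows.append(x[members].mean(axis=0))
        x = np.stack(rows)
        labels = order
    elif level != "specimen":
        raise ValueError(f"unknown PCA level {level!r}")

    n = x.shape[0]
    if n < 2:
        raise MorphosignalError("PCA needs at least 2 rows (after averaging)")
    mean = x.mean(axis=0)
    centered = x - mean
    # SVD route: eigenvalues of cov = s^2 / (n - 1), numerically stable
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt
    # deterministic sign: largest-|.| element of each loading positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = centered @ loadings.T
    total = eigenvalues.sum()
    proportions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapePCAResult(
        mean_vector=mean,
        eigenvalues=eigenvalues,
        proportions=proportions,
        scores=scores,
        loadings=loadings,
        level=level,
        row_labels=labels,
    )


def variance_report(result: ShapePCAResult, top: int | None = None) -> pd.DataFrame:
    """Eigenvalue table for the first ``top`` axes.

    Columns: component, eigenvalue, percent of total variance, cumulative
    percent.  Formatted values (3 significant digits, one decimal on
    percentages) sit alongside full-precision columns.
    """
    m = result.n_components if top is None else int(top)
    if m > result.n_components:
        raise MorphosignalError(
            f"top={m} exceeds the {result.n_components} available components"
        )
    pct = 100.0 * result.proportions
    frame = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(m)],
            "eigenvalue": result.eigenvalues[:m],
            "percent": pct[:m],
            "cumulative_percent": np.cumsum(pct)[:m],
        }
    )
    frame["eigenvalue_fmt"] = [f"{v:.3g}" for v in frame["eigenvalue"]]
    frame["percent_fmt"] = [f"{v:.1f}" for v in frame["percent"]]
    return frame
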