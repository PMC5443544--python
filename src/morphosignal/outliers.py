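"""Multivariate outlier screening via Mahalanobis distance vs chi-squared.

Squared Mahalanobis distances of shape variables are compared to the
chi-squared distribution whose degrees of freedom equal the working
dimension.  Superimposed 2-D shape data are rank-deficient (at most 2k - 4
informative dimensions), so distances are computed on PCA scores in a
full-rank subspace: either every eigenvalue above 1e-12 x the largest, or a
caller-fixed dimension m.  Flagging never deletes data; exclusion is an
explicit pipeline step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DimensionError

RANK_TOL = 1e-12


@dataclass
class OutlierReport:
    specimen_ids: list[str]
    distances: np.ndarray            # squared Mahalanobis D^2 per specimen
    reference_quantiles: np.ndarray  # chi-squared quantiles matched to sorted D^2
    flagged: list[str]               # ids with D^2 above the cutoff quantile
    subspace_dim: int
    cutoff_prob: float

    def qq_pairs(self) -> np.ndarray:
        """(n, 2) array of (chi-squared quantile, ordered D^2) for QQ plots."""
        return np.column_stack([self.reference_quantiles, np.sort(self.distances)])


def mahalanobis_screen(
    data: np.ndarray,
    ids: list[str] | None = None,
    cutoff_prob: float = 0.975,
    subspace: str | int = "full_rank",
) -> OutlierReport:
    """Flag rows whose D^2 exceeds the chi-squared quantile at ``cutoff_prob``.

    ``subspace='full_rank'`` keeps all covariance eigenvalues above
    1e-12 x the largest; an integer fixes the dimension m (raising
    :class:`DimensionError` with the usable rank when the covariance is
    singular there).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be an n x p matrix")
    if not 0.0 < cutoff_prob < 1.0:
        raise ValueError("cutoff_prob must lie in (0, 1)")
    n = x.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]

    centered = x - x.mean(axis=0)
    # eigen-decomposition of the sample covariance via SVD of the data
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / max(n - 1, 1)
    usable = int(np.sum(eigenvalues > RANK_TOL * eigenvalues[0])) if eigenvalues.size else 0

    if subspace == "full_rank":
        m = usable
    else:
        m = int(subspace)
        if m > usable:
            raise DimensionError(
                f"requested subspace dimension {m} exceeds the usable rank "
                f"{usable} of the covariance",
                usable_rank=usable,
            )
    if m < 1:
        raise DimensionError("data have no variance; nothing to screen", usable_rank=0)
    if n <= m + 1:
        raise DimensionError(
            f"need n > m + 1 specimens for an m={m} screen, got n={n}",
            usable_rank=max(n - 2, 0),
        )

    scores = centered @ vt[:m].T
    d2 = np.sum(scores**2 / eigenvalues[:m], axis=1)
    cutoff = stats.chi2.ppf(cutoff_prob, df=m)
    flagged = [ids[i] for i in range(n) if d2[i] > cutoff]
    qq = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=m)
    return OutlierReport(
        specimen_ids=list(ids),
        distances=d2,
        reference_quantiles=qq,
        flagged=flagged,
        subspace_dim=m,
        cutoff_prob=cutoff_prob,
    )


def screen_tangent(
    tangent: np.ndarray,
    specimen_ids: list[str],
    species_ids: list[str] | None = None,
    per_species: bool = True,
    cutoff_prob: float = 0.975,
    subspace: str | int = "full_rank",
) -> list[OutlierReport]:
    """Screen tangent coordinates, by default one report per species.

    Per-species screening compares each specimen against its own species'
    covariance, which is how morphometric outliers are usually defined;
    ``per_species=False`` pools everything into a single report.
    """
    if not per_species or species_ids is None:
        return [
            mahalanobis_screen(tangent, ids=specimen_ids,
                               cutoff_prob=cutoff_prob, subspace=subspace)
        ]
    reports = []
    order: list[str] = []
    for s in species_ids:
        if s not in order:
            order.append(s)
    for s in order:
        rows = [i for i, sp in enumerate(species_ids) if sp == s]
        reports.append(
            mahalanobis_screen(
                tangent[rows],
                ids=[specimen_ids[i] for i in rows],
                cutoff_prob=cutoff_prob,
                subspace=subspace,
            )
        )
    return reports
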