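"""Iterative Mahalanobis-distance outlier clipping (MD-IC).

Procedure, applied per freshness class by default: project the spectra onto
the leading principal components (enough to explain a target fraction of
variance, capped), compute each sample's Mahalanobis distance to the class
mean in score space, and exclude every sample whose distance deviates from
the mean distance by at least three standard deviations (the PauTa / 3-sigma
rule). PCA, distances and the threshold are then recomputed on the survivors
and the clip repeats until an iteration excludes nothing.

The default "distance" is the quadratic form (x - xbar) S^-1 (x - xbar)^T
without a square root; the classical square-rooted Mahalanobis distance is
available via ``squared=False``. The 3-sigma clip operates on whichever
statistic is produced, and sigma uses the population form (1/m under the
root). Samples exactly on the threshold are excluded (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

from .dataio import SpectraDataset, subset
from .errors import InsufficientDataError, SingularCovarianceError

DEFAULT_VARIANCE_THRESHOLD = 0.9999
DEFAULT_MAX_COMPONENTS = 20
DEFAULT_MAX_ITERATIONS = 20

#: relative tolerance below which the distance spread counts as degenerate
_SIGMA_TOL = 1e-12


@dataclass
class IterationRecord:
    """One clipping pass: threshold statistics and who was excluded."""

    mu: float
    sigma: float
    threshold_3sigma: float
    excluded_ids: list
    n_components: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "threshold_3sigma": self.threshold_3sigma,
            "excluded_ids": list(self.excluded_ids),
            "n_components": self.n_components,
            "degenerate": self.degenerate,
        }


@dataclass
class OutlierReport:
    """Full MD-IC trace for one class (or the pooled dataset)."""

    iterations: list = field(default_factory=list)
    n_components_used: int = 0
    converged: bool = False
    total_excluded: int = 0
    class_label: str | None = None

    def excluded_ids(self) -> list:
        out: list = []
        for it in self.iterations:
            out.extend(it.excluded_ids)
        return out

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "iterations": [it.to_dict() for it in self.iterations],
            "n_components_used": self.n_components_used,
            "converged": self.converged,
            "total_excluded": self.total_excluded,
        }


def pca_scores(
    X: np.ndarray,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> np.ndarray:
    """Centered projections onto the leading principal axes.

    The number of retained components k is the smallest k whose cumulative
    explained variance reaches ``variance_threshold``, capped at
    ``max_components`` and at m - 1.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if m < 2:
        raise InsufficientDataError("PCA needs at least 2 samples")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    cap = min(max_components, m - 1, X.shape[1])
    pca = PCA(n_components=min(m - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-15) + 1)
    k = min(k, cap)
    return scores[:, :k]


def mahalanobis_distances(
    S: np.ndarray,
    squared: bool = True,
    pseudo_inverse: bool = False,
) -> np.ndarray:
    """Mahalanobis statistic of each row of ``S`` to the sample mean.

    Covariance uses the m - 1 denominator. By default returns the quadratic
    form (no square root); pass ``squared=False`` for the classical rooted
    distance. A singular covariance raises unless ``pseudo_inverse=True`` is
    requested explicitly.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    m, k = S.shape
    if m <= k:
        raise InsufficientDataError(
            f"need more samples ({m}) than score dimensions ({k}) for an "
            "invertible covariance; lower the number of PCA components"
        )
    center = S - S.mean(axis=0)
    cov = center.T @ center / (m - 1)
    if pseudo_inverse:
        sol = np.linalg.pinv(cov) @ center.T
    else:
        try:
            cho = linalg.cho_factor(cov)
            sol = linalg.cho_solve(cho, center.T)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                "covariance matrix is singular; lower the number of PCA "
                "components or pass pseudo_inverse=True"
            ) from exc
    d2 = np.einsum("ij,ji->i", center, sol)
    d2 = np.maximum(d2, 0.0)
    return d2 if squared else np.sqrt(d2)


def pauta_clip_once(
    distances: np.ndarray | Sequence[float],
) -> tuple[np.ndarray, np.ndarray, float, float, float, bool]:
    """One PauTa (3-sigma) clip of a distance vector.

    Returns ``(kept_idx, excluded_idx, mu, sigma, threshold, degenerate)``.
    mu is the mean distance and sigma its population standard deviation
    (1/m inside the root); sample i is excluded iff |d_i - mu| >= 3 sigma.
    When the distances are (numerically) all equal, sigma is 0, the rule can
    never fire, and the pass is flagged degenerate with no exclusions.
    """
    d = np.asarray(distances, dtype=float)
    m = d.size
    if m < 3:
        raise InsufficientDataError("PauTa clipping needs at least 3 distances")
    mu = float(d.mean())
    sigma = float(np.sqrt(np.mean((d - mu) ** 2)))
    threshold = 3.0 * sigma
    if sigma <= _SIGMA_TOL * max(1.0, abs(mu)):
        return np.arange(m), np.empty(0, dtype=int), mu, sigma, threshold, True
    mask = np.abs(d - mu) >= threshold
    return np.flatnonzero(~mask), np.flatnonzero(mask), mu, sigma, threshold, False


def _mdic_one_group(
    dataset: SpectraDataset,
    variance_threshold: float,
    max_components: int,
    max_iterations: int,
    squared: bool,
    class_label: str | None,
) -> tuple[np.ndarray, OutlierReport]:
    """Run the iterative clip on one group; returns surviving row indices
    (into ``dataset``) and the report."""
    report = OutlierReport(class_label=class_label)
    alive = np.arange(dataset.n_samples)
    for _ in range(max_iterations):
        m_cur = alive.size
        if m_cur < 4:
            raise InsufficientDataError(
                f"group {class_label!r} shrank to {m_cur} samples; "
                "cannot continue MD-IC"
            )
        # cap k at m-2 so the score covariance stays invertible
        k_cap = min(max_components, m_cur - 2)
        S = pca_scores(dataset.X[alive], variance_threshold, k_cap)
        d = mahalanobis_distances(S, squared=squared)
        kept, excl, mu, sigma, thr, degenerate = pauta_clip_once(d)
        report.iterations.append(
            IterationRecord(
                mu=mu,
                sigma=sigma,
                threshold_3sigma=thr,
                excluded_ids=[dataset.sample_ids[alive[i]] for i in excl],
                n_components=S.shape[1],
                degenerate=degenerate,
            )
        )
        report.n_components_used = S.shape[1]
        alive = alive[kept]
        if excl.size == 0:
            report.converged = True
            break
    report.total_excluded = sum(len(it.excluded_ids) for it in report.iterations)
    return alive, report


def mdic_filter(
    dataset: SpectraDataset,
    per_class: bool = True,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    squared: bool = True,
) -> tuple[SpectraDataset, dict[str, OutlierReport]]:
    """Iteratively clip outliers; returns survivors and per-group reports.

    With ``per_class=True`` (default) each freshness class is clipped
    independently, so a class-wide shift is not mistaken for outlyingness.
    The returned dataset contains the original spectra (not PCA scores) of
    all surviving samples in their original order. If ``max_iterations``
    passes never reach a no-exclusion iteration the report has
    ``converged=False``; no exception is raised.
    """
    groups: list[tuple[str | None, SpectraDataset, np.ndarray]] = []
    if per_class:
        for lab in sorted(set(map(str, dataset.label))):
            idx = np.flatnonzero(dataset.label == lab)
            groups.append((lab, subset(dataset, indices=idx), idx))
    else:
        groups.append((None, dataset, np.arange(dataset.n_samples)))

    reports: dict[str, OutlierReport] = {}
    survivor_rows: list[np.ndarray] = []
    for lab, sub, idx in groups:
        alive_local, report = _mdic_one_group(
            sub, variance_threshold, max_components, max_iterations, squared, lab
        )
        reports[lab if lab is not None else "all"] = report
        survivor_rows.append(idx[alive_local])

    keep = np.sort(np.concatenate(survivor_rows))
    return subset(dataset, indices=keep), reports
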