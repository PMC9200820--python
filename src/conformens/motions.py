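"""Cartesian PCA of aligned ensembles and cross-ensemble comparison.

Collective motions are extracted by eigendecomposition of the covariance of
the flattened, aligned Cartesian coordinates ("essential dynamics").  The
fitted model can project any topology-matching ensemble — e.g. an MD
reference trajectory — onto the learned components after superposing each
conformation onto the PCA mean, giving per-model scores along each motion.
Agreement between two ensembles along a component is scored as the overlap
coefficient of their score densities (Gaussian KDE, Silverman bandwidth):
the integral of the pointwise minimum of the two normalised densities,
between 0 (disjoint) and 1 (identical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .core import Ensemble
from .geometry import kabsch_superpose

__all__ = [
    "EnsemblePCA",
    "ProjectionSeries",
    "fit_cartesian_pca",
    "project_models",
    "density_overlap",
]


def _flatten(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 3:
        return coords.reshape(coords.shape[0], -1)
    if coords.ndim == 2:
        return coords
    raise ValueError("expected (n_models, n_atoms, 3) or (n_models, 3N) array")


class EnsemblePCA(TransformerMixin, BaseEstimator):
    """PCA over flattened Cartesian coordinates of an aligned ensemble.

    scikit-learn style transformer.  ``fit(X)`` expects coordinates of an
    already-aligned ensemble, shape ``(n_models, n_atoms, 3)`` or flattened
    ``(n_models, 3N)``.  ``transform(X)`` superposes each conformation onto
    the fitted mean (Kabsch) before projecting, so ensembles expressed in a
    different laboratory frame can be compared in the fitted motion space.

    Components follow a fixed sign convention (the largest-magnitude entry
    of each component is positive) so projections are reproducible.

    Attributes
    ----------
    mean_ : ndarray, shape (3N,)
        Mean conformation, Å.
    components_ : ndarray, shape (n_components, 3N)
        Orthonormal collective-motion basis, sorted by decreasing variance.
    explained_variance_ : ndarray
        Per-component variance of the fitting scores, Å² (ddof = 1).
    explained_variance_ratio_ : ndarray
        Fraction of total variance per component (NaN when the ensemble has
        zero total variance, flagged with a warning).
    """

    def __init__(self, n_components: int | None = None, superpose: bool = True) -> None:
        self.n_components = n_components
        self.superpose = superpose

    def fit(self, X, y=None):
        flat = _flatten(X)
        n, p = flat.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 models")
        n_comp = self.n_components or min(n - 1, p)
        pca = PCA(n_components=n_comp)
        with np.errstate(invalid="ignore"):  # all-identical input: 0/0 ratio
            pca.fit(flat)
        components = pca.components_.copy()
        # sign convention: largest-magnitude entry positive
        for row in components:
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                row *= -1.0
        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_
        total = self.explained_variance_.sum()
        if total > 0:
            self.explained_variance_ratio_ = self.explained_variance_ / total
        else:
            warnings.warn(
                "all models identical: variance fractions undefined",
                stacklevel=2,
            )
            self.explained_variance_ratio_ = np.full(n_comp, np.nan)
        self.n_atoms_ = p // 3
        return self

    # domain-named aliases mirroring the fitted quantities
    @property
    def mean_coords(self) -> np.ndarray:
        return self.mean_

    @property
    def variances(self) -> np.ndarray:
        return self.explained_variance_

    @property
    def variance_fraction(self) -> np.ndarray:
        return self.explained_variance_ratio_

    def transform(self, X) -> np.ndarray:
        """Scores of each conformation along every component, Å."""
        flat = _flatten(X)
        if flat.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"topology mismatch: {flat.shape[1] // 3} atoms vs "
                f"fitted {self.n_atoms_}"
            )
        mean3 = self.mean_.reshape(-1, 3)
        rows = []
        for conf in flat:
            c3 = conf.reshape(-1, 3)
            if self.superpose:
                c3 = kabsch_superpose(c3, mean3).apply(c3)
            rows.append((c3.ravel() - self.mean_) @ self.components_.T)
        return np.array(rows)


@dataclass
class ProjectionSeries:
    """Per-model scores along one principal component, Å."""

    model_ids: list[str]
    scores: np.ndarray
    component: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.model_ids),):
            raise ValueError("scores length must match model_ids")
        self.scores = s

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_id": self.model_ids,
                "component": self.component,
                "score_A": self.scores,
            }
        )


def fit_cartesian_pca(aligned: Ensemble, n_components: int | None = None) -> EnsemblePCA:
    """Fit :class:`EnsemblePCA` on an aligned ensemble's coordinates."""
    return EnsemblePCA(n_components=n_components).fit(aligned.coords())


def project_models(
    pc: EnsemblePCA, ensemble: Ensemble, component: int = 1
) -> ProjectionSeries:
    """Project an ensemble onto one fitted component (1-based index)."""
    if not 1 <= component <= pc.components_.shape[0]:
        raise ValueError(
            f"component {component} out of range 1..{pc.components_.shape[0]}"
        )
    scores = pc.transform(ensemble.coords())[:, component - 1]
    return ProjectionSeries(ensemble.model_ids, scores, component)


def density_overlap(
    scores_a: ProjectionSeries | np.ndarray,
    scores_b: ProjectionSeries | np.ndarray,
    grid_points: int = 512,
    degenerate_tol: float = 1e-6,
) -> float:
    """Overlap coefficient of two score distributions, in [0, 1].

    Gaussian KDEs (Silverman bandwidth) of both series are evaluated on a
    shared grid spanning ``min - 3h`` to ``max + 3h`` (h = the larger
    bandwidth); the overlap is the integral of the pointwise minimum of the
    two densities.  Each KDE is normalised, so unequal sample counts do not
    bias the coefficient.

    A series with (near-)zero variance has no KDE; it is treated as a point
    mass and the overlap falls back to the other density's mass within
    ``+-degenerate_tol`` of that point (1 or 0 when both are degenerate).
    """
    a = np.asarray(scores_a.scores if isinstance(scores_a, ProjectionSeries) else scores_a, dtype=float)
    b = np.asarray(scores_b.scores if isinstance(scores_b, ProjectionSeries) else scores_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("density overlap needs at least 5 points per series")
    a_degenerate = np.ptp(a) < degenerate_tol
    b_degenerate = np.ptp(b) < degenerate_tol
    if a_degenerate and b_degenerate:
        return 1.0 if abs(a.mean() - b.mean()) <= degenerate_tol else 0.0
    if a_degenerate or b_degenerate:
        point = a.mean() if a_degenerate else b.mean()
        kde = gaussian_kde(b if a_degenerate else a, bw_method="silverman")
        return float(kde.integrate_box_1d(point - degenerate_tol, point + degenerate_tol))
    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    h = max(np.sqrt(kde_a.covariance[0, 0]), np.sqrt(kde_b.covariance[0, 0]))
    lo = min(a.min(), b.min()) - 3 * h
    hi = max(a.max(), b.max()) + 3 * h
    grid = np.linspace(lo, hi, grid_points)
    fa = kde_a(grid)
    fb = kde_b(grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))
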