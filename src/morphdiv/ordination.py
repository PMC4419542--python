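"""Tangent-space principal components of species-mean shapes.

After Procrustes superimposition the aligned coordinates live close to the
tangent plane of shape space at the consensus, where ordinary Euclidean
multivariate statistics apply. PCA is run on species means (one point per
species in the morphospace), on the covariance matrix — coordinates share
units, so no correlation scaling — with divisor n - 1.

A 2D configuration of k points loses 4 degrees of freedom to the similarity
transform removed by alignment (2 translation, 1 rotation, 1 scale), so at
most ``min(n_species - 1, 2k - 4)`` axes are informative. Axis signs are
fixed so each axis's largest-magnitude loading is positive: downstream
distances are sign-invariant, but serialized scores must be reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .align import SpeciesMeanSet

__all__ = ["TangentPCA", "TangentSpace", "tangent_pca", "select_axes"]


class TangentPCA(BaseEstimator, TransformerMixin):
    """PCA of flattened shape coordinates with shape-space axis budgeting.

    Parameters
    ----------
    n_components : int, optional
        Cap on the number of retained axes; defaults to the informative
        maximum ``min(n - 1, p - similarity_dof)``.
    similarity_dof : int, default 4
        Degrees of freedom removed by superimposition (2D similarity).

    Attributes
    ----------
    mean_ : ndarray of shape (p,)
        Grand mean of the flattened input.
    components_ : ndarray of shape (m, p)
        Orthonormal axes, descending eigenvalue order, sign-fixed.
    explained_variance_ : ndarray of shape (m,)
        Eigenvalues (divisor n - 1), non-negative, descending.
    explained_variance_ratio_ : ndarray of shape (m,)
        Eigenvalue shares of the total variance.
    total_variance_ : float
        Total variance of the centred input (sum of all eigenvalues).
    """

    def __init__(self, n_components: int | None = None, similarity_dof: int = 4):
        self.n_components = n_components
        self.similarity_dof = similarity_dof

    def _flatten(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if X.ndim != 2:
            raise ValueError("X must be (n, p) or (n, k, 2)")
        return X

    def fit(self, X, y=None):
        X = self._flatten(X)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        max_axes = min(n - 1, max(p - self.similarity_dof, 1))
        if self.n_components is not None:
            max_axes = min(max_axes, int(self.n_components))
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        eig = S**2 / (n - 1)
        m = min(max_axes, len(eig))
        components = Vt[:m]
        # deterministic sign: largest-magnitude loading positive
        idx = np.argmax(np.abs(components), axis=1)
        signs = np.sign(components[np.arange(m), idx])
        signs[signs == 0] = 1.0
        self.components_ = components * signs[:, None]
        self.explained_variance_ = eig[:m]
        self.total_variance_ = float((Xc**2).sum() / (n - 1))
        if self.total_variance_ > 0.0:
            self.explained_variance_ratio_ = self.explained_variance_ / self.total_variance_
        else:
            self.explained_variance_ratio_ = np.zeros(m)
        self.n_samples_ = n
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("TangentPCA instance is not fitted yet")
        X = self._flatten(X)
        return (X - self.mean_) @ self.components_.T


@dataclasses.dataclass
class TangentSpace:
    """Species-mean morphospace: axes, eigenvalues and per-species scores."""

    species: list[str]
    family: list[str]
    grand_mean: np.ndarray  # (2k,)
    axes: np.ndarray  # (m_axes, 2k), orthonormal rows
    eigenvalues: np.ndarray  # descending, >= 0
    proportions: np.ndarray  # shares of total variance
    scores: np.ndarray  # (n_species, m_axes)
    retained: int  # axes reaching the variance threshold


def tangent_pca(species_mean_set: SpeciesMeanSet, threshold: float = 0.95) -> TangentSpace:
    """Principal components of species-mean shapes.

    Flattens each species mean to a 2k-vector, centres by the grand mean and
    eigendecomposes the covariance. ``retained`` is the smallest number of
    leading axes whose cumulative variance share reaches ``threshold``.
    """
    X = species_mean_set.flattened()
    if len(X) < 2:
        raise ValueError("need at least 2 species")
    est = TangentPCA().fit(X)
    scores = est.transform(X)
    try:
        retained = select_axes(est.explained_variance_ratio_, threshold)
    except ValueError:  # no variation at all: keep one (zero-variance) axis
        retained = 1
    return TangentSpace(
        species=list(species_mean_set.species),
        family=list(species_mean_set.family),
        grand_mean=est.mean_,
        axes=est.components_,
        eigenvalues=est.explained_variance_,
        proportions=est.explained_variance_ratio_,
        scores=scores,
        retained=retained,
    )


def select_axes(proportions, threshold: float = 0.95) -> int:
    """Smallest number of leading axes with cumulative variance >= threshold.

    The boundary is inclusive: an axis reaching exactly the threshold is
    retained. Accepts a :class:`TangentSpace` or an array of proportions.
    """
    if isinstance(proportions, TangentSpace):
        proportions = proportions.proportions
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    props = np.asarray(proportions, dtype=float)
    total = props.sum()
    if total <= 0.0:
        raise ValueError("no variation: all eigenvalue proportions are zero")
    cum = np.cumsum(props)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    if len(hit) == 0:  # threshold above attainable cumulative share
        return int(np.count_nonzero(props > 0.0))
    return int(hit[0]) + 1
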