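"""Condition-level 2-D embeddings of shift / rewiring feature matrices.

Rows are conditions, columns are features (per-marker signed EMDs or
per-pair ΔDREMI).  Two embeddings are provided: plain PCA, and a
diffusion-potential embedding — an adaptive-bandwidth α-decay kernel is
row-normalised into a Markov transition matrix, powered ``t`` steps, and
the −log transition probabilities ("potential distances") are laid out in
2-D by metric MDS.  The diffusion embedding preserves both local and
global structure of the condition landscape at the desk scale (tens to
hundreds of conditions) without any scalability machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import smacof
from sklearn.utils.validation import check_array, check_is_fitted

POTENTIAL_FLOOR = 1e-7


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-magnitude loading positive."""
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    return components, scores


class PCAEmbedding(TransformerMixin, BaseEstimator):
    """Column-centered PCA with a deterministic sign convention."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = check_array(X)
        if X.shape[0] < self.n_components:
            raise ValueError(
                f"need at least {self.n_components} rows, got {X.shape[0]}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        components, scores = _fix_signs(pca.components_.copy(), scores)
        self.components_ = components
        self.mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_features_in_ = X.shape[1]
        return scores

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return (X - self.mean_) @ self.components_.T


def _classical_mds_init(dist: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson classical scaling; deterministic, permutation-equivariant."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
    _, coords = _fix_signs(coords.T.copy(), coords.copy())
    return coords


class DiffusionPotentialEmbedding(BaseEstimator):
    """Diffusion-potential condition embedding.

    Pipeline: pairwise Euclidean distances; adaptive-bandwidth α-decay
    kernel ``K_ij = exp(-(d_ij/σ_i)^α)`` with ``σ_i`` the distance to the
    k-th nearest row, symmetrised; row-normalised Markov matrix powered to
    ``t``; potential coordinates ``-log(P^t)`` (floored at 1e-7); metric MDS
    to 2-D seeded from classical scaling.  Deterministic for a fixed seed.
    """

    def __init__(
        self,
        k: int = 5,
        alpha: float = 10.0,
        t: int = 10,
        n_components: int = 2,
        random_state: int = 42,
    ):
        self.k = k
        self.alpha = alpha
        self.t = t
        self.n_components = n_components
        self.random_state = random_state

    def fit_transform(self, X, y=None):
        X = check_array(X)
        n = X.shape[0]
        if n < 3:
            raise ValueError("diffusion embedding needs at least 3 rows")
        if self.k >= n:
            raise ValueError(f"k={self.k} must be smaller than the number of rows {n}")

        D = squareform(pdist(X))
        # σ_i: distance to the k-th nearest other row
        sigma = np.sort(D, axis=1)[:, self.k]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sigma[:, None] > 0, D / np.maximum(sigma[:, None], 1e-300), np.inf)
            K = np.exp(-(ratio**self.alpha))
        K[D == 0] = 1.0  # identical rows (and the diagonal) are fully connected
        K = 0.5 * (K + K.T)
        P = K / K.sum(axis=1, keepdims=True)
        Pt = np.linalg.matrix_power(P, self.t)
        potential = -np.log(np.clip(Pt, POTENTIAL_FLOOR, None))

        pot_dist = squareform(pdist(potential))
        init = _classical_mds_init(pot_dist, self.n_components)
        coords, stress = smacof(
            pot_dist,
            n_components=self.n_components,
            init=init,
            n_init=1,
            random_state=self.random_state,
            normalized_stress=False,
        )
        self.potential_ = potential
        self.stress_ = float(stress)
        self.embedding_ = coords
        return coords

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self


def embed_conditions(
    matrix: pd.DataFrame,
    method: str = "diffusion",
    **settings,
) -> pd.DataFrame:
    """Embed a conditions × features matrix to 2-D.

    Missing values are zero-filled (with a logged count) before embedding.
    Returns a DataFrame (condition, dim1, dim2, method).
    """
    X = matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        import logging

        logging.getLogger(__name__).warning(
            "zero-filled %d missing feature values before embedding", n_missing
        )
        X = np.nan_to_num(X, nan=0.0)
    if method == "pca":
        coords = PCAEmbedding(n_components=2, **settings).fit_transform(X)
    elif method == "diffusion":
        coords = DiffusionPotentialEmbedding(n_components=2, **settings).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(
        {
            "condition": list(matrix.index),
            "dim1": coords[:, 0],
            "dim2": coords[:, 1],
            "method": method,
        }
    )
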