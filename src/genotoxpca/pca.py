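"""Correlation-matrix PCA with deterministic orientation.

The projection used throughout is

    Y_k = sum_p a_kp * (x_p - mu_p) / sigma_p

where ``x_p`` is a gene's mean log2(exp/cont) ratio, ``mu_p``/``sigma_p``
are that gene's mean and sample standard deviation over the fitting rows,
and ``a_kp`` are the rows of an orthonormal eigenvector matrix of the
per-gene correlation matrix. Eigenvector signs are arbitrary, so a fitted
model is oriented deterministically: PC1 points so that coordinate
induction of the marker genes gives *negative* scores (the genotoxic
signature), matching the published sign convention.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateInputError, DomainError
from .reference import FOUR_GENES
from .types import ChemClass, RatioMatrix


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, RatioMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return pd.DataFrame(arr)


def standardize(matrix, ddof: int = 1):
    """Column-wise z-scoring; returns ``(Z, mu, sigma)`` as pandas objects.

    Raises :class:`DegenerateInputError` naming the first zero-variance gene.
    """
    df = _as_frame(matrix)
    if len(df) < 2:
        raise DomainError("standardization needs at least 2 rows")
    mu = df.mean(axis=0)
    sigma = df.std(axis=0, ddof=ddof)
    bad = sigma[~(sigma > 0)]
    if len(bad):
        raise DegenerateInputError(
            f"gene {bad.index[0]!r} has zero variance across rows"
        )
    return (df - mu) / sigma, mu, sigma


class StandardizedPCA(TransformerMixin, BaseEstimator):
    """PCA on the per-gene correlation matrix, with stored mu/sigma.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep (default: all = number of genes).
    orient : {"loading-sum", "labels", "none"}
        Sign convention. ``"loading-sum"`` flips PC1 so its loadings sum to
        a negative value; ``"labels"`` flips PC1 so the mean score of rows
        labeled GTHC (passed as ``y`` to :meth:`fit`) is negative. In both
        modes, when the panel is the four consensus marker genes, PC2 is
        flipped so its Cdkn1a loading is negative, matching the published
        vector's dominant entry. ``"none"`` keeps raw eigenvector signs
        (first nonzero coefficient positive).
    ddof : int
        Divisor convention for the standard deviation (1 = sample SD).

    Attributes
    ----------
    mu_, sigma_ : ndarray of shape (n_genes,)
    components_ : ndarray of shape (n_components, n_genes)
        Orthonormal loading rows, sorted by descending eigenvalue.
    explained_variance_ : ndarray
        Eigenvalues of the correlation matrix (score variances, sample
        convention).
    orientation_flips_ : ndarray
        +-1 per component, the sign applied relative to the canonical
        (first-nonzero-positive) eigenvectors.
    """

    def __init__(self, n_components: int | None = None,
                 orient: str = "loading-sum", ddof: int = 1):
        self.n_components = n_components
        self.orient = orient
        self.ddof = ddof

    # -- construction from published constants ---------------------------

    @classmethod
    def from_constants(cls, feature_names, mu, sigma, components,
                       explained_variance=None) -> "StandardizedPCA":
        """Build an already-'fitted' model from fixed printed constants."""
        model = cls(orient="none")
        model.feature_names_in_ = np.asarray(list(feature_names), dtype=object)
        model.n_features_in_ = len(model.feature_names_in_)
        model.mu_ = np.asarray(mu, dtype=float)
        model.sigma_ = np.asarray(sigma, dtype=float)
        if not (model.sigma_ > 0).all():
            raise DomainError("sigma must be strictly positive")
        model.components_ = np.atleast_2d(np.asarray(components, dtype=float))
        if explained_variance is None:
            explained_variance = np.full(model.components_.shape[0], np.nan)
        model.explained_variance_ = np.asarray(explained_variance, dtype=float)
        model.orientation_flips_ = np.ones(model.components_.shape[0])
        return model

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None) -> "StandardizedPCA":
        df = _as_frame(X)
        if len(df) < 2:
            raise DomainError("PCA needs at least 2 rows")
        Z, mu, sigma = standardize(df, ddof=self.ddof)
        n, p = Z.shape
        corr = (Z.to_numpy().T @ Z.to_numpy()) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(-eigvals, kind="stable")
        eigvals = eigvals[order]
        eigvecs = eigvecs[:, order].T  # rows = components

        # canonical sign: first nonzero coefficient of each row positive
        for k in range(eigvecs.shape[0]):
            nz = np.flatnonzero(np.abs(eigvecs[k]) > 1e-12)
            if len(nz) and eigvecs[k, nz[0]] < 0:
                eigvecs[k] = -eigvecs[k]

        k_keep = self.n_components or p
        k_keep = min(k_keep, p)
        self.feature_names_in_ = np.asarray(list(df.columns), dtype=object)
        self.n_features_in_ = p
        self.mu_ = mu.to_numpy()
        self.sigma_ = sigma.to_numpy()
        self.components_ = eigvecs[:k_keep]
        self.explained_variance_ = eigvals[:k_keep]
        self.orientation_flips_ = np.ones(k_keep)
        self._apply_orientation(df, y)
        return self

    def _apply_orientation(self, df: pd.DataFrame, y) -> None:
        if self.orient == "none":
            return
        if self.orient not in ("loading-sum", "labels"):
            raise DomainError(f"unknown orientation mode: {self.orient!r}")
        flips = np.ones(self.components_.shape[0])

        # PC1: genotoxic signature scores negative
        flip_pc1 = False
        if self.orient == "labels" and y is not None:
            if isinstance(y, pd.Series) and set(y.index) == set(df.index):
                labels = y.reindex(df.index)
            else:
                labels = pd.Series(list(y), index=df.index)
            gthc_rows = labels[
                labels.map(lambda v: ChemClass(v) is ChemClass.GTHC)
            ].index
            if len(gthc_rows):
                scores = self._raw_scores(df)
                if scores.loc[gthc_rows].iloc[:, 0].mean() > 0:
                    flip_pc1 = True
            else:
                flip_pc1 = self.components_[0].sum() > 0
        else:
            flip_pc1 = self.components_[0].sum() > 0
        if flip_pc1:
            flips[0] = -1

        # PC2 on the four-gene panel: Cdkn1a loading negative
        if (
            self.components_.shape[0] >= 2
            and tuple(self.feature_names_in_) == FOUR_GENES
        ):
            j = list(self.feature_names_in_).index("Cdkn1a")
            if self.components_[1, j] * flips[1] > 0:
                flips[1] = -flips[1]

        self.components_ = self.components_ * flips[:, None]
        self.orientation_flips_ = flips

    def _raw_scores(self, df: pd.DataFrame) -> pd.DataFrame:
        Z = (df.to_numpy(dtype=float) - self.mu_) / self.sigma_
        return pd.DataFrame(Z @ self.components_.T, index=df.index)

    # -- projection --------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Project rows onto the components using the stored mu/sigma."""
        check_is_fitted(self, "components_")
        df = _as_frame(X)
        if isinstance(df.columns, pd.Index) and df.columns.dtype == object:
            cols = [str(c) for c in df.columns]
            want = [str(c) for c in self.feature_names_in_]
            if set(cols) != set(want):
                raise DomainError(
                    f"gene panel mismatch: model expects {want}, got {cols}"
                )
            df = df.loc[:, want]
        elif df.shape[1] != self.n_features_in_:
            raise DomainError(
                f"expected {self.n_features_in_} genes, got {df.shape[1]}"
            )
        Z = (df.to_numpy(dtype=float) - self.mu_) / self.sigma_
        return Z @ self.components_.T

    def score_frame(self, X) -> pd.DataFrame:
        """Scores as a DataFrame with ``pc1``, ``pc2``, ... columns."""
        df = _as_frame(X)
        scores = self.transform(df)
        cols = [f"pc{k + 1}" for k in range(scores.shape[1])]
        return pd.DataFrame(scores, index=df.index, columns=cols)

    def flip_component(self, k: int) -> "StandardizedPCA":
        """Negate component *k* in place (scores negate accordingly)."""
        check_is_fitted(self, "components_")
        self.components_[k] = -self.components_[k]
        self.orientation_flips_[k] = -self.orientation_flips_[k]
        return self


def fit_pca(matrix, orient: str = "loading-sum", labels=None,
            n_components: int | None = None) -> StandardizedPCA:
    """Functional wrapper: fit an oriented correlation-matrix PCA."""
    mode = "labels" if labels is not None else orient
    return StandardizedPCA(n_components=n_components, orient=mode).fit(
        _as_frame(matrix), y=labels
    )


def project(model: StandardizedPCA, matrix) -> pd.DataFrame:
    """Project a ratio matrix with a fitted (or constant) model."""
    return model.score_frame(_as_frame(matrix))
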