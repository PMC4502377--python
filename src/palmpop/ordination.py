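"""Principal components analysis of genotypes with 1/2/3 coding.

Genotypes are coded homozygous-reference = 1, heterozygous = 2,
homozygous-alternative = 3; missing calls are imputed with the column mean
of the observed codes, columns with no observed calls are dropped, and the
coded matrix is column-centred (no unit-variance scaling) before an SVD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import MISSING, GenotypeMatrix


def encode_genotypes(gm) -> np.ndarray:
    """Code dosages 0/1/2 as 1/2/3; impute missing with the column mean.

    Columns that are entirely missing carry no information and are removed
    (with a warning).
    """
    dosage = gm.dosage if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    called = dosage != MISSING
    codes = np.where(called, dosage + 1, 0).astype(float)
    n_obs = called.sum(axis=0)
    keep = n_obs > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-missing loci before PCA")
    codes, called, n_obs = codes[:, keep], called[:, keep], n_obs[keep]
    col_mean = codes.sum(axis=0) / n_obs
    codes[~called] = np.broadcast_to(col_mean, codes.shape)[~called]
    return codes


@dataclass
class PcaResult:
    scores: np.ndarray  # (N, n_components)
    variance_fraction: np.ndarray
    components: np.ndarray  # (n_components, L)


class GenotypePCA(BaseEstimator, TransformerMixin):
    """PCA over 1/2/3-coded genotypes (scikit-learn transformer interface).

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_ : ndarray (n_samples, n_components)
    variance_fraction_ : ndarray — fraction of total variance per component
    components_ : ndarray (n_components, n_loci_used)
    mean_ : ndarray — column means of the coded matrix
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        codes = encode_genotypes(X) if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
        n, m = codes.shape
        if n < 2:
            raise ValueError("PCA needs at least two samples")
        k = min(self.n_components, n, m)
        self.mean_ = codes.mean(axis=0)
        centred = codes - self.mean_
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        total = float((s**2).sum())
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        self.variance_fraction_ = (
            (s[:k] ** 2) / total if total > 0 else np.zeros(k)
        )
        self.scores_ = u[:, :k] * s[:k]
        self.n_features_in_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        codes = encode_genotypes(X) if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
        return (codes - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_


def run_pca(encoded: np.ndarray, n_components: int = 10) -> PcaResult:
    """Functional wrapper over :class:`GenotypePCA` for a coded matrix."""
    model = GenotypePCA(n_components=n_components).fit(np.asarray(encoded, float))
    return PcaResult(
        scores=model.scores_,
        variance_fraction=model.variance_fraction_,
        components=model.components_,
    )
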