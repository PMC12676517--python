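"""PCA-LDA chemometrics baseline.

PCA (scikit-learn) reduces the corrected spectra to the smallest number of
components reaching a cumulative explained-variance target; a two-class
Fisher discriminant is then fit in PC space with the closed form
direction ∝ S_w^{-1}(mu_disease - mu_control) and a midpoint threshold
(equal class priors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .spectral_data import SpectrumSet

#: ridge added to a singular within-class scatter: eps = RIDGE_FACTOR * trace / dims
RIDGE_FACTOR = 1e-6


@dataclass
class PCAProjection:
    mean: np.ndarray
    components: np.ndarray               # (k, n_wavenumbers), orthonormal rows
    explained_variance_ratio: np.ndarray

    def transform(self, intensities: np.ndarray) -> np.ndarray:
        return (np.asarray(intensities, dtype=float) - self.mean) @ self.components.T


@dataclass
class LDAModel:
    direction: np.ndarray   # unit vector in PC space
    threshold: float
    class_means: tuple[np.ndarray, np.ndarray]  # (control, disease)


def fit_pca(train: SpectrumSet, variance_target: float = 0.99) -> PCAProjection:
    """PCA on training spectra; keep the smallest k reaching the variance target."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    X = train.intensities
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training spectra")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training set: all spectra identical")
    pca = PCA(svd_solver="full").fit(X)
    # drop numerically-zero directions so k never exceeds the centered rank
    nonzero = pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]
    ratios = pca.explained_variance_ratio_[nonzero]
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, ratios.size, X.shape[0] - 1)
    return PCAProjection(
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_variance_ratio=ratios[:k],
    )


def fit_lda(scores: np.ndarray, labels: np.ndarray) -> LDAModel:
    """Two-class Fisher discriminant: direction ∝ S_w^{-1}(mu_d - mu_c).

    ``labels`` is 0 (control) / 1 (disease).  A singular pooled within-class
    scatter is ridge-regularized with eps = 1e-6 * trace(S_w)/dims.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    Xc, Xd = scores[labels == 0], scores[labels == 1]
    mu_c, mu_d = Xc.mean(axis=0), Xd.mean(axis=0)
    Sw = (Xc - mu_c).T @ (Xc - mu_c) + (Xd - mu_d).T @ (Xd - mu_d)
    dims = Sw.shape[0]
    try:
        direction = np.linalg.solve(Sw, mu_d - mu_c)
    except np.linalg.LinAlgError:
        direction = None
    if direction is None or not np.all(np.isfinite(direction)) or np.linalg.cond(
        Sw
    ) > 1e12:
        eps = RIDGE_FACTOR * np.trace(Sw) / dims
        if eps <= 0:
            eps = RIDGE_FACTOR
        direction = np.linalg.solve(Sw + eps * np.eye(dims), mu_d - mu_c)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("degenerate LDA: identical class means")
    direction = direction / norm
    threshold = float(direction @ (mu_c + mu_d) / 2.0)
    return LDAModel(direction=direction, threshold=threshold, class_means=(mu_c, mu_d))


def predict_lda(
    model: LDAModel, pca: PCAProjection, data: SpectrumSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum (class, score).  Class 1 (disease) iff score > threshold.

    A score exactly at the threshold is called control (conservative
    tie-break for a positive-screen label).
    """
    if data.intensities.shape[1] != pca.components.shape[1]:
        raise ValueError("grid length does not match the fitted PCA")
    scores = pca.transform(data.intensities) @ model.direction
    return (scores > model.threshold).astype(int), scores
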