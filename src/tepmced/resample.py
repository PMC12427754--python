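"""Minority oversampling (SMOTE) and the resample -> scale -> classify pipeline.

SMOTE balances the classes by interpolating synthetic minority points
between each minority sample and one of its k nearest minority neighbors
(k = 5 by default). Resampling happens only at fit time — synthetic points
never leave the training side of a fold — and the scaler statistics are
computed on the resampled training data, matching the fixed pipeline order
resample -> scale -> classify.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


class SMOTE:
    """Synthetic minority oversampling with k-NN interpolation.

    Upsamples the minority class to match the majority count. With fewer
    than 2 minority samples, falls back to resampling with replacement.
    """

    def __init__(self, k_neighbors: int = 5, seed: int = 0) -> None:
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("SMOTE expects exactly two classes")
        minority = classes[int(np.argmin(counts))]
        n_needed = int(counts.max() - counts.min())
        if n_needed == 0:
            return X.copy(), y.copy()
        rng = np.random.default_rng(self.seed)
        Xm = X[y == minority]
        if Xm.shape[0] < 2:
            idx = rng.integers(0, Xm.shape[0], size=n_needed)
            synth = Xm[idx]
        else:
            k = min(self.k_neighbors, Xm.shape[0] - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
            _, neigh = nn.kneighbors(Xm)  # first column is the point itself
            base_idx = rng.integers(0, Xm.shape[0], size=n_needed)
            pick = rng.integers(1, k + 1, size=n_needed)
            partner = neigh[base_idx, pick]
            u = rng.random((n_needed, 1))
            synth = Xm[base_idx] + u * (Xm[partner] - Xm[base_idx])
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        return X_out, y_out


class _ArrayScaler:
    """Z-score scaler on ndarray (sd=0 columns map to 0)."""

    def fit(self, X: np.ndarray) -> "_ArrayScaler":
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        Z = (np.asarray(X, dtype=float) - self.mean_) / sd
        Z[:, self.sd_ == 0] = 0.0
        return Z


class ResampleScalePipeline:
    """Fixed-order pipeline: SMOTE (fit only) -> z-score scaler -> classifier.

    ``classifier`` must expose fit(X, y) and predict_proba(X) -> (n, 2).
    """

    def __init__(self, classifier, k_neighbors: int = 5, seed: int = 0, use_smote: bool = True) -> None:
        self.classifier = classifier
        self.k_neighbors = k_neighbors
        self.seed = seed
        self.use_smote = use_smote
        self.scaler_: _ArrayScaler | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ResampleScalePipeline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.use_smote:
            Xr, yr = SMOTE(self.k_neighbors, self.seed).fit_resample(X, y)
        else:
            Xr, yr = X, y
        self.scaler_ = _ArrayScaler().fit(Xr)
        self.classifier.fit(self.scaler_.transform(Xr), yr)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_ is None:
            raise RuntimeError("pipeline not fitted")
        return self.classifier.predict_proba(self.scaler_.transform(np.asarray(X, dtype=float)))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Cancer-class probability."""
        return self.predict_proba(X)[:, 1]
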