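"""Naive Bayes with optional per-feature kernel-density class densities.

A conditional-independence classifier over continuous features. With
``kernel=False`` each class-conditional feature density is a fitted
Gaussian; with ``kernel=True`` it is a one-dimensional Gaussian KDE whose
bandwidth is Silverman's rule-of-thumb times the ``adjust`` multiplier.
``laplace`` (fL) additively smooths the class-prior counts.

Implements the minimal sklearn estimator surface (fit / predict /
predict_proba / get_params / set_params) so it can sit in cross-validation
loops next to the stock classifiers.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, TrainingError

__all__ = ["KernelNaiveBayes"]

_LOG_EPS = -745.0  # log of the smallest positive double, as a density floor


class KernelNaiveBayes:
    def __init__(self, kernel: bool = False, adjust: float = 1.0,
                 laplace: float = 0.0):
        self.kernel = kernel
        self.adjust = adjust
        self.laplace = laplace

    # sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"kernel": self.kernel, "adjust": self.adjust,
                "laplace": self.laplace}

    def set_params(self, **params) -> "KernelNaiveBayes":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    # fitting ----------------------------------------------------------
    def fit(self, X, y) -> "KernelNaiveBayes":
        if self.adjust <= 0:
            raise ConfigurationError("kernel bandwidth multiplier must be > 0")
        if self.laplace < 0:
            raise ConfigurationError("laplace smoothing must be >= 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise TrainingError("need two classes")
        counts = np.array([(y == c).sum() for c in self.classes_], dtype=float)
        prior = (counts + self.laplace) / (counts.sum() + self.laplace * counts.size)
        self.log_prior_ = np.log(prior)
        self._train = []
        for c in self.classes_:
            Xc = X[y == c]
            sd = Xc.std(axis=0, ddof=1) if len(Xc) > 1 else np.zeros(X.shape[1])
            sd = np.where(sd > 0, sd, 1e-9)
            if self.kernel:
                q75, q25 = np.percentile(Xc, [75, 25], axis=0)
                spread = np.minimum(sd, np.where(q75 > q25, (q75 - q25) / 1.34, sd))
                bw = self.adjust * 0.9 * spread * len(Xc) ** (-0.2)
                bw = np.where(bw > 0, bw, 1e-9)
                self._train.append(("kde", Xc, bw))
            else:
                self._train.append(("gauss", Xc.mean(axis=0), sd))
        return self

    def _class_log_density(self, spec, X: np.ndarray) -> np.ndarray:
        kind = spec[0]
        if kind == "gauss":
            _, mu, sd = spec
            z = (X - mu) / sd
            ll = -0.5 * z * z - np.log(sd) - 0.5 * np.log(2 * np.pi)
        else:
            _, Xc, bw = spec
            # density at X[i, j]: mean of N(x; xc, bw_j) over training points
            z = (X[:, None, :] - Xc[None, :, :]) / bw
            k = np.exp(-0.5 * z * z) / (bw * np.sqrt(2 * np.pi))
            ll = np.log(np.maximum(k.mean(axis=1), 1e-300))
        return np.maximum(ll, _LOG_EPS).sum(axis=1)

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([
            self.log_prior_[k] + self._class_log_density(spec, X)
            for k, spec in enumerate(self._train)
        ])

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
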