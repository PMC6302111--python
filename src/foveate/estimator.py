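"""Scikit-learn estimator facade over the active-vision pipeline.

``ActiveFoveaClassifier`` fits the per-(class, viewpoint) gated Gaussian
bank on labeled images and classifies new images by simulated saccadic
exploration: each prediction runs the evidence-accumulation loop under
the configured action-selection metric and stopping threshold, so the
classifier reads only a fraction of each image's coefficients.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .emission import FitConfig, fit_model_bank, image_log_likelihood, make_faulty
from .policies import (
    ExplorationResult,
    build_trajectories,
    explore_scene,
    precompute_action_maps,
)
from .pyramid import haar_decompose, pad_image

__all__ = ["ActiveFoveaClassifier"]


def _as_images(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        n, d = X.shape
        if d == 784:
            X = X.reshape(n, 28, 28)
        elif d == 1024:
            X = X.reshape(n, 32, 32)
        else:
            raise ValueError(f"flattened images must have 784 or 1024 features, got {d}")
    if X.ndim != 3 or X.shape[1:] not in ((28, 28), (32, 32)):
        raise ValueError(f"X must be (n, 28, 28) or (n, 32, 32) images, got {X.shape}")
    return X


class ActiveFoveaClassifier(ClassifierMixin, BaseEstimator):
    """Saccadic scene-decoding classifier.

    Parameters
    ----------
    metric : str, default "iglb"
        Action-selection objective (one of ``foveate.metrics.METRIC_IDS``).
    h_ref : float, default 1e-4
        Entropy stopping threshold in nats; lower reads more evidence.
    policy : str, default "smooth"
        "smooth" (full prediction-based selection), "sharp"
        (single-guess prediction), "trajectories"/"generic_trajectory"
        (pre-processed scan paths) or "random".
    predict_mode : str, default "sample"
        Candidate-field prediction: seeded draw ("sample") or density
        mode ("mode").
    faulty : bool, default False
        Corrupt the fitted bank by forcing every Bernoulli gate open
        (robustness protocol).
    laplace_a, white_eps, reg_lambda
        Fitting hyper-parameters, see :class:`foveate.emission.FitConfig`.
    random_state : int or None
        Seed for every stochastic component of exploration.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    bank_ : fitted :class:`foveate.emission.ModelBank`.
    """

    def __init__(
        self,
        metric: str = "iglb",
        h_ref: float = 1e-4,
        policy: str = "smooth",
        predict_mode: str = "sample",
        faulty: bool = False,
        laplace_a: float = 1.0,
        white_eps: float = 1e-9,
        reg_lambda: float | None = None,
        random_state: int | None = 0,
    ) -> None:
        self.metric = metric
        self.h_ref = h_ref
        self.policy = policy
        self.predict_mode = predict_mode
        self.faulty = faulty
        self.laplace_a = laplace_a
        self.white_eps = white_eps
        self.reg_lambda = reg_lambda
        self.random_state = random_state

    def fit(self, X, y) -> "ActiveFoveaClassifier":
        images = _as_images(X)
        y = np.asarray(y)
        if len(images) != len(y):
            raise ValueError("X and y length mismatch")
        cfg = FitConfig(
            laplace_a=self.laplace_a,
            white_eps=self.white_eps,
            reg_lambda=self.reg_lambda,
        )
        bank = fit_model_bank(list(images), y, cfg)
        if self.faulty:
            bank = make_faulty(bank)
        self.bank_ = bank
        self.classes_ = bank.classes
        self.n_features_in_ = X.shape[1] if np.asarray(X).ndim == 2 else None
        self.trajectories_ = None
        return self

    def _table(self):
        if self.policy in ("trajectories", "generic_trajectory"):
            if self.trajectories_ is None:
                maps, generic = precompute_action_maps(self.bank_)
                self.trajectories_ = build_trajectories(maps, generic)
            return self.trajectories_
        return None

    def explore(self, image, seed: int | None = None) -> ExplorationResult:
        """Run one full exploration episode on a single image."""
        check_is_fitted(self, "bank_")
        pyr = haar_decompose(pad_image(np.asarray(image, dtype=float)))
        return explore_scene(
            pyr,
            self.bank_,
            metric=self.metric,
            h_ref=self.h_ref,
            policy=self.policy,
            predict_mode=self.predict_mode,
            seed=self.random_state if seed is None else seed,
            table=self._table(),
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "bank_")
        images = _as_images(X)
        rng = np.random.default_rng(self.random_state)
        out = []
        for img in images:
            out.append(self.explore(img, seed=rng).predicted)
        return np.asarray(out)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "bank_")
        images = _as_images(X)
        rng = np.random.default_rng(self.random_state)
        probs = np.empty((len(images), len(self.classes_)))
        for k, img in enumerate(images):
            res = self.explore(img, seed=rng)
            probs[k] = res.posterior_trace[-1].probs
        return probs

    def full_information_log_likelihood(self, X) -> np.ndarray:
        """Per-class log-likelihood using every coefficient (no saccades).

        The argmax plus the log class prior is the full-information
        reference classifier against which exploration is benchmarked.
        """
        check_is_fitted(self, "bank_")
        images = _as_images(X)
        out = np.empty((len(images), len(self.classes_)))
        for k, img in enumerate(images):
            pyr = haar_decompose(pad_image(img))
            out[k] = image_log_likelihood(pyr, self.bank_) + np.log(
                self.bank_.class_prior
            )
        return out
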