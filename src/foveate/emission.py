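"""Bernoulli-gated Gaussian emission model, per (class, viewpoint).

For every latent category ``z`` and pyramid viewpoint ``u`` the triplet
observed at ``u`` is modeled as

    x ~ B(rho_{z,u}) x N(mu_{z,u}, Sigma_{z,u})

a "gate then emit" mixture: with probability ``1 - rho`` the triplet is
*white* (exactly zero, as Haar details of blank image regions are), and
with probability ``rho`` it is a 3-variate Gaussian draw.  The gate
captures the alternating presence/absence of stroke energy at high
frequencies and at the image periphery; the Gaussian captures the shape
statistics where energy is present.

A :class:`ModelBank` holds one parameter set per (class, viewpoint) over
all 341 viewpoints, a per-class univariate Gaussian on the root
approximation coefficient (the source of the initial guess), and the
empirical class prior.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pyramid import (
    N_DETAIL_VIEWPOINTS,
    MultiscaleField,
    Viewpoint,
    WaveletPyramid,
    haar_decompose,
    pad_image,
    vp_index,
)

__all__ = [
    "FitConfig",
    "EmissionParams",
    "ModelBank",
    "fit_gated_gaussian",
    "fit_model_bank",
    "triplet_log_likelihood",
    "field_log_likelihood",
    "field_log_likelihood_vector",
    "image_log_likelihood",
    "predict_view",
    "make_faulty",
    "save_bank",
    "load_bank",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitConfig:
    """Fitting hyper-parameters.

    laplace_a
        Pseudo-count of the Beta(a, a) smoothing prior on each gate.
    white_eps
        A triplet is *white* when all three |coefficients| < white_eps.
        Haar details of zero-background regions are exactly zero, so a
        near-machine threshold suffices.
    reg_lambda
        Diagonal loading added to every fitted covariance.  ``None``
        selects ``1e-4`` times the mean per-pixel variance of the
        training images, keeping the floor on the data's own scale.
    delta
        Underflow guard inside the gate log-likelihood branches.
    """

    laplace_a: float = 1.0
    white_eps: float = 1e-9
    reg_lambda: float | None = None
    delta: float = 1e-12


@dataclass(frozen=True)
class EmissionParams:
    """Parameters (rho, mu, Sigma) of one gated Gaussian."""

    rho: float
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != (3,) or sigma.shape != (3, 3):
            raise ValueError("mu must be (3,) and sigma (3, 3)")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass
class ModelBank:
    """Per-(class, viewpoint) emission parameters plus root model and prior.

    Array layout: ``classes`` has length Z; ``rho`` is (Z, 341), ``mu``
    is (Z, 341, 3), ``sigma`` is (Z, 341, 3, 3), root moments and the
    class prior are length-Z vectors.  Viewpoints are in flat
    :func:`foveate.pyramid.vp_index` order.
    """

    classes: np.ndarray
    rho: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    root_mean: np.ndarray
    root_var: np.ndarray
    class_prior: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)
    train_hashes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        z = len(self.classes)
        v = N_DETAIL_VIEWPOINTS
        assert self.rho.shape == (z, v)
        assert self.mu.shape == (z, v, 3)
        assert self.sigma.shape == (z, v, 3, 3)
        assert abs(self.class_prior.sum() - 1.0) < 1e-9
        self._cache: dict[str, np.ndarray] = {}

    # -- derived arrays, cached -------------------------------------------
    def _derived(self, key: str) -> np.ndarray:
        if key not in self._cache:
            chol = np.linalg.cholesky(self.sigma)
            self._cache["chol"] = chol
            self._cache["prec"] = np.linalg.inv(self.sigma)
            self._cache["logdet"] = 2.0 * np.log(
                np.diagonal(chol, axis1=-2, axis2=-1)
            ).sum(axis=-1)
        return self._cache[key]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self, z) -> int:
        idx = np.nonzero(self.classes == z)[0]
        if idx.size == 0:
            raise KeyError(f"unknown class: {z!r}")
        return int(idx[0])

    def params(self, z, u: Viewpoint) -> EmissionParams:
        zi, ui = self.class_index(z), vp_index(Viewpoint(*u))
        return EmissionParams(
            rho=float(self.rho[zi, ui]), mu=self.mu[zi, ui], sigma=self.sigma[zi, ui]
        )

    def mode_triplets(self) -> np.ndarray:
        """Mode of every gated density, (Z, 341, 3): mu where rho >= 0.5,
        the white triplet elsewhere.  The argmax of a mixed mass/density
        is ill-posed; this majority-gate convention is the one used for
        pre-processed action maps."""
        if "mode" not in self._cache:
            out = np.where(self.rho[..., None] >= 0.5, self.mu, 0.0)
            self._cache["mode"] = out
        return self._cache["mode"]

    def loglik_dense_all(self, x: np.ndarray) -> np.ndarray:
        """Gated log-likelihood of triplets ``x`` of shape (..., 341, 3)
        under every class: returns (..., Z, 341).

        The leading dims of ``x`` broadcast; the viewpoint axis must be
        full.  Used by the vectorized policy scorer.
        """
        eps = self.config.white_eps
        delta = self.config.delta
        prec = self._derived("prec")  # (Z, V, 3, 3)
        logdet = self._derived("logdet")  # (Z, V)
        xw = np.all(np.abs(x) < eps, axis=-1)  # (..., V)
        d = x[..., None, :, :] - self.mu  # (..., Z, V, 3)
        maha = np.einsum("...zvi,zvij,...zvj->...zv", d, prec, d, optimize=True)
        dense = np.log(self.rho + delta) - 0.5 * (maha + logdet + 3.0 * _LOG_2PI)
        white = np.log(1.0 - self.rho + delta)  # (Z, V)
        return np.where(xw[..., None, :], white, dense)

    def root_log_likelihood(self, root: float) -> np.ndarray:
        """log N(root; root_mean_z, root_var_z) for every class."""
        return -0.5 * (
            np.log(2.0 * np.pi * self.root_var)
            + (root - self.root_mean) ** 2 / self.root_var
        )


def _images_to_flat(images: Sequence[np.ndarray]) -> np.ndarray:
    """Decompose images to the flat (n, 1024) pyramid representation."""
    flats = np.empty((len(images), 1 + 3 * N_DETAIL_VIEWPOINTS))
    for k, img in enumerate(images):
        flats[k] = haar_decompose(pad_image(img)).to_array()
    return flats


def _hash_image(img: np.ndarray) -> bytes:
    return hashlib.sha1(np.ascontiguousarray(img, dtype=np.float64).tobytes()).digest()


def fit_gated_gaussian(
    samples: np.ndarray, config: FitConfig | None = None, reg_lambda: float = 1e-6
) -> EmissionParams:
    """Moment-match one gated Gaussian on raw triplet samples.

    The same estimator the bank fit applies per (class, viewpoint) cell:
    Laplace-smoothed gate on the non-white fraction, Gaussian moments of
    the non-white samples, diagonal covariance loading.
    """
    config = config or FitConfig()
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("samples must have shape (n, 3)")
    n = len(x)
    present = ~np.all(np.abs(x) < config.white_eps, axis=1)
    k = int(present.sum())
    a = config.laplace_a
    rho = (k + a) / (n + 2.0 * a)
    lam = config.reg_lambda if config.reg_lambda is not None else reg_lambda
    if k == 0:
        return EmissionParams(rho=rho, mu=np.zeros(3), sigma=lam * np.eye(3))
    xp = x[present]
    mu = xp.mean(axis=0)
    d = xp - mu
    sigma = (d.T @ d) / k + lam * np.eye(3)
    return EmissionParams(rho=rho, mu=mu, sigma=sigma)


def fit_model_bank(
    images: Sequence[np.ndarray],
    labels: Sequence,
    config: FitConfig | None = None,
) -> ModelBank:
    """Fit one gated Gaussian per (class, viewpoint) by moment matching.

    For each class and viewpoint the gate is the Laplace-smoothed
    fraction of non-white training triplets, and the Gaussian moments
    are computed over the non-white triplets only ("discarding the white
    triplets"), with diagonal covariance loading.  A class/viewpoint
    cell with no non-white triplet falls back to (mu=0, Sigma=lambda*I).
    """
    config = config or FitConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    padded = [pad_image(img) for img in images]
    flat = _images_to_flat(padded)
    n, _ = flat.shape

    stack = np.stack(padded)
    lam = config.reg_lambda
    if lam is None:
        lam = 1e-4 * float(stack.var(axis=0).mean())
        if lam <= 0.0:
            lam = 1e-8

    V = N_DETAIL_VIEWPOINTS
    X = flat[:, 1:].reshape(n, V, 3)
    white = np.all(np.abs(X) < config.white_eps, axis=-1)  # (n, V)

    Z = len(classes)
    rho = np.empty((Z, V))
    mu = np.zeros((Z, V, 3))
    sigma = np.tile(lam * np.eye(3), (Z, V, 1, 1))
    root_mean = np.empty(Z)
    root_var = np.empty(Z)
    prior = np.empty(Z)
    a = config.laplace_a

    for zi, z in enumerate(classes):
        sel = labels == z
        nz = int(sel.sum())
        if nz < 2:
            raise ValueError(f"class {z!r} has fewer than 2 training examples")
        Xz = X[sel]  # (nz, V, 3)
        w = ~white[sel]  # non-white mask (nz, V)
        counts = w.sum(axis=0)  # (V,)
        rho[zi] = (counts + a) / (nz + 2.0 * a)
        wf = w.astype(float)
        safe = np.maximum(counts, 1)
        m = np.einsum("nv,nvi->vi", wf, Xz) / safe[:, None]
        d = (Xz - m) * wf[..., None]
        cov = np.einsum("nvi,nvj->vij", d, d) / safe[:, None, None]
        has = counts > 0
        mu[zi, has] = m[has]
        sigma[zi, has] = cov[has] + lam * np.eye(3)
        root_mean[zi] = flat[sel, 0].mean()
        root_var[zi] = max(flat[sel, 0].var(), lam)
        prior[zi] = nz / n

    return ModelBank(
        classes=classes,
        rho=rho,
        mu=mu,
        sigma=sigma,
        root_mean=root_mean,
        root_var=root_var,
        class_prior=prior,
        # record the resolved regularization floor for provenance
        config=replace(config, reg_lambda=lam),
        train_hashes=frozenset(_hash_image(img) for img in padded),
    )


def is_white(x: np.ndarray, eps: float = 1e-9) -> bool:
    x = np.asarray(x, dtype=float)
    return bool(np.all(np.abs(x) < eps))


def triplet_log_likelihood(
    x: np.ndarray,
    params: EmissionParams,
    *,
    white_eps: float = 1e-9,
    delta: float = 1e-12,
) -> float:
    """Gated log-likelihood of one triplet.

    White branch: ``log(1 - rho + delta)``; present branch:
    ``log(rho + delta) + log N(x; mu, Sigma)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValueError("triplet must be 3 finite values")
    if is_white(x, white_eps):
        return float(np.log(1.0 - params.rho + delta))
    diff = x - params.mu
    sign, logdet = np.linalg.slogdet(params.sigma)
    if sign <= 0:
        raise ValueError("sigma is not positive definite")
    maha = float(diff @ np.linalg.solve(params.sigma, diff))
    return float(
        np.log(params.rho + delta) - 0.5 * (maha + logdet + 3.0 * _LOG_2PI)
    )


def field_log_likelihood(field: MultiscaleField, z, bank: ModelBank) -> float:
    """Log-likelihood of a foveated field under class ``z``.

    Triplets are conditionally independent given the class, so the field
    log-likelihood is the sum over its (unconsumed) triplets; an empty
    field contributes no evidence (0).
    """
    zi = bank.class_index(z)
    eps, delta = bank.config.white_eps, bank.config.delta
    total = 0.0
    for vp, x in field.triplets:
        total += triplet_log_likelihood(
            np.asarray(x),
            EmissionParams(
                rho=float(bank.rho[zi, vp_index(vp)]),
                mu=bank.mu[zi, vp_index(vp)],
                sigma=bank.sigma[zi, vp_index(vp)],
            ),
            white_eps=eps,
            delta=delta,
        )
    return total


def field_log_likelihood_vector(field: MultiscaleField, bank: ModelBank) -> np.ndarray:
    """``log p(field | z, u)`` for every class, vectorized; (Z,)."""
    if len(field) == 0:
        return np.zeros(bank.n_classes)
    idx = np.array([vp_index(vp) for vp, _ in field.triplets])
    x = np.stack([np.asarray(t, dtype=float) for _, t in field.triplets])  # (T, 3)
    eps, delta = bank.config.white_eps, bank.config.delta
    prec = bank._derived("prec")[:, idx]  # (Z, T, 3, 3)
    logdet = bank._derived("logdet")[:, idx]  # (Z, T)
    rho = bank.rho[:, idx]
    muz = bank.mu[:, idx]
    xw = np.all(np.abs(x) < eps, axis=-1)  # (T,)
    d = x[None] - muz  # (Z, T, 3)
    maha = np.einsum("zti,ztij,ztj->zt", d, prec, d)
    dense = np.log(rho + delta) - 0.5 * (maha + logdet + 3.0 * _LOG_2PI)
    white_ll = np.log(1.0 - rho + delta)
    return np.where(xw[None, :], white_ll, dense).sum(axis=1)


def image_log_likelihood(
    pyramid: WaveletPyramid, bank: ModelBank, include_root: bool = True
) -> np.ndarray:
    """Full-information log-likelihood per class: all 341 triplets
    (+ optionally the root coefficient model).  The argmax of this vector
    plus the log class prior is the full-information classifier."""
    ll = bank.loglik_dense_all(pyramid.details).sum(axis=-1)
    if include_root:
        ll = ll + bank.root_log_likelihood(pyramid.root)
    return ll


def predict_view(
    z,
    u: Viewpoint,
    bank: ModelBank,
    mode: str = "sample",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Predict the triplet a class would emit at a viewpoint.

    ``mode="sample"`` draws presence from the gate then a Gaussian
    triplet (a seed or Generator is mandatory: prediction is part of the
    reproducibility contract); ``mode="mode"`` returns the gated-density
    mode (mu if rho >= 0.5, else the white triplet).
    """
    p = bank.params(z, u)
    if mode == "mode":
        return p.mu.copy() if p.rho >= 0.5 else np.zeros(3)
    if mode == "sample":
        if seed is None:
            raise ValueError("sample mode requires an explicit seed or Generator")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        if rng.random() >= p.rho:
            return np.zeros(3)
        return rng.multivariate_normal(p.mu, p.sigma, method="cholesky")
    raise ValueError(f"unknown prediction mode: {mode!r}")


def make_faulty(bank: ModelBank) -> ModelBank:
    """Corrupted copy with every gate forced open (rho = 1).

    The faulty model predicts dense signal in effectively sparse regions
    while mu, Sigma, root models and prior stay bitwise identical, so any
    behavioral difference is attributable to the gate alone.  Idempotent.
    """
    return ModelBank(
        classes=bank.classes.copy(),
        rho=np.ones_like(bank.rho),
        mu=bank.mu.copy(),
        sigma=bank.sigma.copy(),
        root_mean=bank.root_mean.copy(),
        root_var=bank.root_var.copy(),
        class_prior=bank.class_prior.copy(),
        config=bank.config,
        train_hashes=bank.train_hashes,
    )


def save_bank(bank: ModelBank, path) -> None:
    np.savez_compressed(
        path,
        classes=bank.classes,
        rho=bank.rho,
        mu=bank.mu,
        sigma=bank.sigma,
        root_mean=bank.root_mean,
        root_var=bank.root_var,
        class_prior=bank.class_prior,
        config=np.array(
            [
                bank.config.laplace_a,
                bank.config.white_eps,
                -1.0 if bank.config.reg_lambda is None else bank.config.reg_lambda,
                bank.config.delta,
            ]
        ),
    )


def load_bank(path) -> ModelBank:
    with np.load(path, allow_pickle=False) as f:
        a, eps, lam, delta = f["config"]
        return ModelBank(
            classes=f["classes"],
            rho=f["rho"],
            mu=f["mu"],
            sigma=f["sigma"],
            root_mean=f["root_mean"],
            root_var=f["root_var"],
            class_prior=f["class_prior"],
            config=FitConfig(
                laplace_a=float(a),
                white_eps=float(eps),
                reg_lambda=None if lam < 0 else float(lam),
                delta=float(delta),
            ),
        )
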