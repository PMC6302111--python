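"""Sequential Bayesian posterior maintenance over the category set.

The belief is a probability vector q over the finite latent set Z.  New
foveated observations multiply in through Bayes' rule,

    q_new(z)  propto  p(x | z, u) * q(z)

computed in log space with max-subtraction, so chaining many small
fields is numerically identical to conditioning on their union at once.
All entropies and divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .emission import ModelBank, field_log_likelihood_vector
from .pyramid import MultiscaleField, WaveletPyramid

__all__ = [
    "Belief",
    "init_prior",
    "update_belief",
    "belief_entropy",
    "one_view_posterior",
    "posterior_from_log",
]


@dataclass(frozen=True)
class Belief:
    """A normalized probability vector over the latent categories.

    Carries the normalized log-probabilities alongside the probabilities
    so that chained Bayes updates keep full precision: a category whose
    probability underflows to 0 in linear space still has a finite,
    usable log-probability when built via :func:`posterior_from_log`.
    """

    probs: np.ndarray
    log_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("belief must be a non-empty vector")
        if np.any(p < 0) or not np.isfinite(p).all():
            raise ValueError("belief probabilities must be finite and >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"belief must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "probs", p)
        if self.log_probs is None:
            with np.errstate(divide="ignore"):
                object.__setattr__(self, "log_probs", np.log(p))
        else:
            object.__setattr__(self, "log_probs", np.asarray(self.log_probs, float))

    @classmethod
    def uniform(cls, n: int) -> "Belief":
        return cls(np.full(n, 1.0 / n))

    def entropy(self) -> float:
        return belief_entropy(self)

    def argmax(self) -> int:
        return int(np.argmax(self.probs))

    def __len__(self) -> int:
        return self.probs.size


def posterior_from_log(log_unnorm: np.ndarray) -> Belief:
    """Normalize unnormalized log-probabilities into a Belief.

    A fully degenerate vector (all -inf) is surfaced as an error rather
    than silently renormalized.
    """
    log_unnorm = np.asarray(log_unnorm, dtype=float)
    norm = logsumexp(log_unnorm)
    if not np.isfinite(norm):
        raise FloatingPointError("all log-odds are -inf; posterior undefined")
    logp = log_unnorm - norm
    return Belief(np.exp(logp), log_probs=logp)


def init_prior(pyramid: WaveletPyramid, bank: ModelBank) -> Belief:
    """Loose initial guess from the root approximation coefficient.

    softmax over z of log N(root; root-model_z) + log prior(z): the root
    coefficient is the image's mean luminance, a weak but free cue read
    before any saccade.
    """
    if bank.root_var is None or not np.all(bank.root_var > 0):
        raise ValueError("bank has no valid root models")
    ll = bank.root_log_likelihood(pyramid.root)
    return posterior_from_log(ll + np.log(bank.class_prior))


def update_belief(prior: Belief, field: MultiscaleField, bank: ModelBank) -> Belief:
    """One step of sequential Bayes: condition the belief on a field."""
    if len(prior) != bank.n_classes:
        raise ValueError("belief dimension does not match the bank")
    if len(field) == 0:
        return prior
    ll = field_log_likelihood_vector(field, bank)
    return posterior_from_log(ll + prior.log_probs)


def belief_entropy(b: Belief) -> float:
    """Shannon entropy in nats, with 0 log 0 = 0; in [0, log |Z|]."""
    p = b.probs
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def one_view_posterior(field: MultiscaleField, bank: ModelBank) -> Belief:
    """Single-view posterior p(Z | x, u) under a uniform prior over Z.

    This is the belief an observer with no history would form from the
    field alone; it is the building block of the information-gain bounds.
    """
    if len(field) == 0:
        return Belief.uniform(bank.n_classes)
    return posterior_from_log(field_log_likelihood_vector(field, bank))
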