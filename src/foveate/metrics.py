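"""Action-selection objectives for saccade choice.

Every candidate saccade is scored from a small context: the running
belief q_prev (and its predecessor q_prev2), the log-likelihood vector
of the last observation, and the log-likelihood vector of the
*predicted* observation at the candidate viewpoint.  All objectives are
exposed as scores to maximize (losses are negated):

================  ====================================================
random            seeded uniform draw (baseline policy)
infomax           H(q_prev) - H(q_next): posterior entropy reduction
saliency          KL(q_next || q_prev): Bayesian surprise
vfe               negated predictive free energy:
                  log-evidence - KL(q_prev || q_next)
ci                compression improvement: the drop in variational
                  reconstruction cost of the *previous* observation
                  brought by the candidate; equals the sequential
                  information gain at the exact posteriors
iglb              E_{z~q_prev}[log p(z | x, u)]: conservative IG bound
iglb_sharp        the same at the single point argmax q_prev
igub              E_{z~q_next}[log p(z | x, u)]: optimistic IG bound
================  ====================================================

The bounds under- and over-estimate the information gain by exactly the
epistemic cost KL(q_prev || q_next) and the salience KL(q_next || q_prev)
respectively; the identities are exact here because the single-view
posterior p(Z | x, u) is taken under a uniform prior over Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .belief import Belief, posterior_from_log

__all__ = [
    "METRIC_IDS",
    "MetricContext",
    "score_candidate",
    "exact_sequential_ig",
    "approximate_ci_kl_form",
    "expected_metric_scores",
    "iglb_kl_form",
    "igub_kl_form",
    "kl_divergence",
]

METRIC_IDS = (
    "random",
    "infomax",
    "saliency",
    "vfe",
    "ci",
    "iglb",
    "iglb_sharp",
    "igub",
)


def kl_divergence(p: Belief, q: Belief) -> float:
    """KL(p || q) in nats with 0 log 0 = 0 (may be +inf if q lacks support)."""
    nz = p.probs > 0
    return float((p.probs[nz] * (p.log_probs[nz] - q.log_probs[nz])).sum())


class ContractViolation(ValueError):
    """A MetricContext whose derived beliefs are not the stated updates."""


@dataclass(frozen=True)
class MetricContext:
    """Everything a metric may consult when scoring one candidate.

    ``loglik_cand`` is log p(x_cand | z, u_cand) per class for the
    predicted candidate observation; ``loglik_last`` the same for the
    observation actually made on the previous saccade.  ``q_next`` must
    be the Bayes update of ``q_prev`` by the candidate likelihood, and
    ``q_skip`` the update of ``q_prev2`` by the candidate's single-view
    posterior (the "skip one step" posterior of the sequential IG).
    """

    q_prev: Belief
    loglik_cand: np.ndarray
    q_next: Belief
    q_prev2: Optional[Belief] = None
    loglik_last: Optional[np.ndarray] = None
    q_skip: Optional[Belief] = None

    def __post_init__(self) -> None:
        expect = posterior_from_log(self.loglik_cand + self.q_prev.log_probs)
        if not np.allclose(expect.probs, self.q_next.probs, atol=1e-8):
            raise ContractViolation("q_next is not the Bayes update of q_prev")
        if self.q_skip is not None:
            if self.q_prev2 is None:
                raise ContractViolation("q_skip given without q_prev2")
            expect = posterior_from_log(
                self.one_view_log_posterior + self.q_prev2.log_probs
            )
            if not np.allclose(expect.probs, self.q_skip.probs, atol=1e-8):
                raise ContractViolation("q_skip is not the update of q_prev2")

    @classmethod
    def from_loglik(
        cls,
        q_prev: Belief,
        loglik_cand: np.ndarray,
        q_prev2: Belief | None = None,
        loglik_last: np.ndarray | None = None,
    ) -> "MetricContext":
        """Build a consistent context, deriving q_next and q_skip."""
        loglik_cand = np.asarray(loglik_cand, dtype=float)
        q_next = posterior_from_log(loglik_cand + q_prev.log_probs)
        q_skip = None
        if q_prev2 is not None:
            ovlp = loglik_cand - logsumexp(loglik_cand)
            q_skip = posterior_from_log(ovlp + q_prev2.log_probs)
        return cls(
            q_prev=q_prev,
            loglik_cand=loglik_cand,
            q_next=q_next,
            q_prev2=q_prev2,
            loglik_last=None if loglik_last is None else np.asarray(loglik_last, float),
            q_skip=q_skip,
        )

    @property
    def one_view_log_posterior(self) -> np.ndarray:
        """log p(z | x_cand, u_cand) under a uniform prior over Z."""
        return self.loglik_cand - logsumexp(self.loglik_cand)

    def _require_history(self, what: str) -> None:
        if self.q_prev2 is None or self.loglik_last is None or self.q_skip is None:
            raise ContractViolation(
                f"{what} requires q_prev2, loglik_last and q_skip in the context"
            )


def _log_evidence(loglik: np.ndarray, q: Belief) -> float:
    """log p(x | u; q) = log sum_z q(z) p(x | z, u)."""
    return float(logsumexp(loglik + q.log_probs))


def score_candidate(
    metric: str,
    ctx: MetricContext,
    rng: np.random.Generator | None = None,
) -> float:
    """Score one candidate action; higher is preferred for every metric."""
    if metric not in METRIC_IDS:
        raise ValueError(f"unknown metric: {metric!r}")
    if metric == "random":
        if rng is None:
            raise ValueError("the random metric requires a seeded Generator")
        return float(rng.random())
    if metric == "infomax":
        return ctx.q_prev.entropy() - ctx.q_next.entropy()
    if metric == "saliency":
        return kl_divergence(ctx.q_next, ctx.q_prev)
    if metric == "vfe":
        # negated predictive free energy: log-evidence minus epistemic cost
        return _log_evidence(ctx.loglik_cand, ctx.q_prev) - kl_divergence(
            ctx.q_prev, ctx.q_next
        )
    ovlp = ctx.one_view_log_posterior
    if metric == "iglb":
        return float(ctx.q_prev.probs @ ovlp)
    if metric == "iglb_sharp":
        return float(ovlp[ctx.q_prev.argmax()])
    if metric == "igub":
        return float(ctx.q_next.probs @ ovlp)
    # metric == "ci": drop in reconstruction cost of the previous
    # observation, evaluated at the exact (pre/post) posteriors.
    ctx._require_history("ci")
    f_before = (
        -float(ctx.q_prev.probs @ ctx.loglik_last)
        + kl_divergence(ctx.q_prev, ctx.q_prev2)
    )
    f_after = (
        -float(ctx.q_next.probs @ ctx.loglik_last)
        + kl_divergence(ctx.q_next, ctx.q_skip)
    )
    return f_before - f_after


def exact_sequential_ig(ctx: MetricContext) -> float:
    """Sequential information gain of the candidate observation.

    The improvement in retrospective log-evidence for the *previous*
    observation when the belief history is rewritten to include the
    candidate: log p(x_last | u_last; q_skip) - log p(x_last | u_last;
    q_prev2).
    """
    ctx._require_history("exact_sequential_ig")
    return _log_evidence(ctx.loglik_last, ctx.q_skip) - _log_evidence(
        ctx.loglik_last, ctx.q_prev2
    )


def approximate_ci_kl_form(ctx: MetricContext, q: Belief) -> float:
    """KL-difference form of the approximate compression improvement,
    KL(q || q_prev2) - KL(q || q_skip), for an arbitrary pivot q.

    Unlike the score forms (which drop an additive normalizer that is
    genuinely action-independent only when the second-back belief is
    uniform), this form obeys the exact bound identities against the
    sequential information gain.
    """
    ctx._require_history("approximate_ci_kl_form")
    return kl_divergence(q, ctx.q_prev2) - kl_divergence(q, ctx.q_skip)


def expected_metric_scores(
    emission: np.ndarray,
    q_prev: Belief,
    metric: str,
    q_prev2: Belief | None = None,
    loglik_last: np.ndarray | None = None,
) -> np.ndarray:
    """Exact predicted score of every action in an enumerable world.

    ``emission[z, u, x]`` is a finite observation table; the returned
    vector is E_{z ~ q_prev, x ~ p(x|z,u)}[score(x, u)] per action —
    the full-expectation form of prediction-based action selection,
    tractable here because the observation space is finite.
    """
    emission = np.asarray(emission, dtype=float)
    Z, U, X = emission.shape
    out = np.empty(U)
    with np.errstate(divide="ignore"):
        log_em = np.log(emission)
    for u in range(U):
        total = 0.0
        for x in range(X):
            p_x = float(emission[:, u, x] @ q_prev.probs)
            if p_x == 0.0:
                continue
            ctx = MetricContext.from_loglik(
                q_prev, log_em[:, u, x], q_prev2, loglik_last
            )
            total += p_x * score_candidate(metric, ctx)
        out[u] = total
    return out


def iglb_kl_form(ctx: MetricContext) -> float:
    """Conservative bound: underestimates the IG by KL(q_prev || q_next)."""
    return approximate_ci_kl_form(ctx, ctx.q_prev)


def igub_kl_form(ctx: MetricContext) -> float:
    """Optimistic bound: overestimates the IG by KL(q_next || q_prev)."""
    return approximate_ci_kl_form(ctx, ctx.q_next)
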