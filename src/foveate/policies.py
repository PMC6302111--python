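"""Saccade selection policies and the scene-exploration loop.

The exploration loop alternates: score every remaining gaze point with
a prediction-based objective, saccade to the best one, read the foveated
field there (inhibition of return: viewpoints already consumed are
skipped and the gaze point leaves the action set), and condition the
belief on the new evidence.  The loop stops when the belief entropy
falls under a threshold H_ref, or when the action set is exhausted.

Prediction-based scoring considers, for each candidate gaze u and each
class z, the field the model *expects* to see there — either a seeded
draw from the gated Gaussians or their mode — and evaluates the chosen
metric on the resulting hypothetical belief update.  The expected score
is the belief-weighted average over z.

Two cheap shortcuts are provided: the *sharp* variant predicts for the
single current best guess only (cost linear in the number of gazes),
and the *pre-processed trajectory* variant reads the next saccade from
a per-class ranking computed offline from the action maps, with an
on-the-fly switch whenever the guess is revised (constant cost per
step, no predictive computation at decision time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .belief import Belief, init_prior, posterior_from_log
from .emission import ModelBank, field_log_likelihood_vector
from .metrics import METRIC_IDS
from .pyramid import (
    CHAIN_INDEX,
    N_DETAIL_VIEWPOINTS,
    GazePoint,
    MultiscaleField,
    Viewpoint,
    WaveletPyramid,
    compression_rates,
    read_field,
    vp_index,
)

__all__ = [
    "ExplorationState",
    "ExplorationResult",
    "ActionMap",
    "TrajectoryTable",
    "ExhaustionError",
    "select_action",
    "explore_scene",
    "precompute_action_maps",
    "build_trajectories",
    "trajectory_policy_step",
    "threshold_readout",
    "save_action_maps",
]

POLICY_IDS = ("smooth", "sharp", "trajectories", "generic_trajectory", "random")


class ExhaustionError(RuntimeError):
    """Raised when an action is requested but no gaze point remains."""


@dataclass
class ExplorationState:
    """Mutable state of one exploration episode."""

    belief: Belief
    belief_prev: Belief            # q^(n-2), consumed by the CI objective
    loglik_last: np.ndarray        # log p(x_last | z, u_last) per class
    action_set: set = field(default_factory=set)
    consumed: set = field(default_factory=set)
    last_field: Optional[MultiscaleField] = None
    step: int = 0
    triplets_read: int = 0
    coefficients_read: int = 0
    n_predictions: int = 0         # emission-model predictions spent on selection
    traj_pos: dict = field(default_factory=dict)

    @classmethod
    def fresh(cls, belief: Belief, prior: Belief, loglik_root: np.ndarray) -> "ExplorationState":
        return cls(
            belief=belief,
            belief_prev=prior,
            loglik_last=np.asarray(loglik_root, dtype=float),
            action_set={GazePoint(i, j) for i in range(16) for j in range(16)},
            coefficients_read=1,  # the root coefficient is read up front
        )


@dataclass(frozen=True)
class ExplorationResult:
    """Outcome of one exploration episode."""

    predicted: object
    saccades: tuple
    posterior_trace: tuple
    n_saccades: int
    compression: tuple            # (coefficient %, triplet %), integer percent
    terminated_by: str            # "threshold" or "exhausted"
    coefficients_read: int
    triplets_read: int
    coefficients_trace: tuple     # cumulative count after each step (incl. start)
    triplets_trace: tuple
    n_predictions: int


def _consumed_mask(consumed: set) -> np.ndarray:
    mask = np.zeros(N_DETAIL_VIEWPOINTS, dtype=bool)
    if consumed:
        mask[[vp_index(Viewpoint(*vp)) for vp in consumed]] = True
    return mask


def _sample_predictions(
    bank: ModelBank, zp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Seeded draw of one predicted triplet per (selected class, viewpoint)."""
    chol = bank._derived("chol")[zp]          # (P, V, 3, 3)
    mu = bank.mu[zp]
    rho = bank.rho[zp]
    present = rng.random(rho.shape) < rho
    eps = rng.standard_normal(mu.shape)
    x = mu + np.einsum("pvij,pvj->pvi", chol, eps)
    return np.where(present[..., None], x, 0.0)


def _entropy_rows(logp: np.ndarray, p: np.ndarray) -> np.ndarray:
    return -(p * np.where(p > 0, logp, 0.0)).sum(axis=-1)


def _score_matrix(
    metric: str,
    L: np.ndarray,
    q_prev: Belief,
    q_prev2: Belief,
    loglik_last: np.ndarray,
) -> np.ndarray:
    """Vectorized metric scores.

    ``L[g, p, e]`` is the log-likelihood under evaluation class ``e`` of
    the field predicted for class ``p`` at candidate gaze ``g``; returns
    the (G, P) score matrix r(z, u).  Matches
    :func:`foveate.metrics.score_candidate` term by term.
    """
    logq_prev = q_prev.log_probs
    lse_next = logsumexp(L + logq_prev, axis=-1)            # (G, P) log-evidence
    logq_next = L + logq_prev - lse_next[..., None]
    q_next = np.exp(logq_next)
    ovlp = L - logsumexp(L, axis=-1, keepdims=True)         # one-view log posterior
    if metric == "infomax":
        return q_prev.entropy() - _entropy_rows(logq_next, q_next)
    if metric == "saliency":
        return (q_next * np.where(q_next > 0, logq_next - logq_prev, 0.0)).sum(axis=-1)
    if metric == "vfe":
        kl = (
            q_prev.probs * np.where(q_prev.probs > 0, logq_prev - logq_next, 0.0)
        ).sum(axis=-1)
        return lse_next - kl
    if metric == "iglb":
        return ovlp @ q_prev.probs
    if metric == "iglb_sharp":
        # the caller restricts the prediction axis to the current guess
        return ovlp[..., q_prev.argmax()]
    if metric == "igub":
        return (q_next * ovlp).sum(axis=-1)
    if metric == "ci":
        logq_prev2 = q_prev2.log_probs
        lse_skip = logsumexp(ovlp + logq_prev2, axis=-1)
        logq_skip = ovlp + logq_prev2 - lse_skip[..., None]
        f_before = -float(q_prev.probs @ loglik_last) + float(
            (
                q_prev.probs
                * np.where(q_prev.probs > 0, logq_prev - logq_prev2, 0.0)
            ).sum()
        )
        f_after = -(q_next * loglik_last).sum(axis=-1) + (
            q_next * np.where(q_next > 0, logq_next - logq_skip, 0.0)
        ).sum(axis=-1)
        return f_before - f_after
    raise ValueError(f"unknown metric: {metric!r}")


def select_action(
    bank: ModelBank,
    state: ExplorationState,
    metric: str,
    predict_mode: str = "sample",
    rng: np.random.Generator | int | None = None,
) -> GazePoint:
    """One prediction-based action choice (highest expected score).

    For every class z and remaining gaze u, the field the model expects
    at u's unconsumed viewpoints is predicted (seeded sample or mode)
    and scored; the returned gaze maximizes the belief-weighted score,
    ties broken toward the lowest (i, j) in row-major order.
    """
    if metric not in METRIC_IDS:
        raise ValueError(f"unknown metric: {metric!r}")
    if not state.action_set:
        raise ExhaustionError("the action set is empty")
    candidates = sorted(state.action_set)
    if rng is not None and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if metric == "random":
        if rng is None:
            raise ValueError("the random metric requires a seeded rng")
        return GazePoint(*candidates[int(rng.integers(len(candidates)))])

    gflat = np.array([16 * i + j for i, j in candidates])
    chains = CHAIN_INDEX[gflat]                             # (G, 5)
    unconsumed = ~_consumed_mask(state.consumed)[chains]    # (G, 5)

    if metric == "iglb_sharp":
        zp = np.array([state.belief.argmax()])
    else:
        zp = np.arange(bank.n_classes)

    if predict_mode == "mode":
        xhat = bank.mode_triplets()[zp]                     # (P, V, 3)
    elif predict_mode == "sample":
        if rng is None:
            raise ValueError("sample prediction requires a seeded rng")
        xhat = _sample_predictions(bank, zp, rng)
    else:
        raise ValueError(f"unknown prediction mode: {predict_mode!r}")

    ll = bank.loglik_dense_all(xhat)                        # (P, Z, V)
    lg = ll[:, :, chains] * unconsumed[None, None, :, :]    # (P, Z, G, 5)
    L = lg.sum(axis=-1).transpose(2, 0, 1)                  # (G, P, Z)
    r = _score_matrix(metric, L, state.belief, state.belief_prev, state.loglik_last)
    state.n_predictions += r.shape[0] * r.shape[1]
    if metric == "iglb_sharp":
        values = r[:, 0]
    else:
        values = r @ state.belief.probs
    return GazePoint(*candidates[int(np.argmax(values))])


@dataclass(frozen=True)
class ActionMap:
    """Expected one-view log posterior of a guess at every gaze point."""

    guess: object                 # class label, or None for the generic map
    values: np.ndarray            # (16, 16)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (16, 16) or not np.isfinite(v).all():
            raise ValueError("action map must be a finite 16x16 grid")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TrajectoryTable:
    """Offline saccade orderings: one per class plus a generic one."""

    per_class: dict
    generic: tuple

    def list_for(self, guess) -> tuple:
        return self.generic if guess is None else self.per_class[guess]


def precompute_action_maps(bank: ModelBank) -> tuple[list[ActionMap], ActionMap]:
    """Guess-consistent action maps from mode predictions.

    For each class the full 5-triplet field expected at every gaze is
    predicted by the mode of the gated density, and the map stores the
    log posterior the guess would receive from that field alone (uniform
    prior).  The generic map is the uniform-prior average over guesses.
    """
    modes = bank.mode_triplets()                            # (Z, V, 3)
    ll = bank.loglik_dense_all(modes)                       # (P, Z, V)
    Lg = ll[:, :, CHAIN_INDEX].sum(axis=-1)                 # (P, Z, G)
    ovlp = Lg - logsumexp(Lg, axis=1, keepdims=True)
    maps = [
        ActionMap(guess=z, values=ovlp[zi, zi].reshape(16, 16))
        for zi, z in enumerate(bank.classes)
    ]
    generic = ActionMap(
        guess=None,
        values=np.mean([m.values for m in maps], axis=0),
    )
    return maps, generic


def build_trajectories(
    maps: Sequence[ActionMap], generic: ActionMap
) -> TrajectoryTable:
    """Sort each map's gaze points by descending value (stable ties in
    row-major order) into ready-to-read saccade lists."""

    def order(m: ActionMap) -> tuple:
        flat = m.values.ravel()
        idx = np.argsort(-flat, kind="stable")
        return tuple(GazePoint(int(k) // 16, int(k) % 16) for k in idx)

    return TrajectoryTable(
        per_class={m.guess: order(m) for m in maps},
        generic=order(generic),
    )


def trajectory_policy_step(
    table: TrajectoryTable,
    state: ExplorationState,
    use_generic_until_guess: bool = True,
    guess_threshold: float | None = None,
    classes: np.ndarray | None = None,
) -> GazePoint:
    """Next saccade from the pre-processed lists, O(1) amortized.

    The list followed is the current guess's; while the belief is still
    near uniform (max below ``guess_threshold``, default 2/|Z|) and the
    flag is set, the generic list is followed instead.  A per-list
    cursor skips entries already consumed, so no predictive computation
    happens at decision time.
    """
    if not state.action_set:
        raise ExhaustionError("the action set is empty")
    n = len(state.belief)
    if guess_threshold is None:
        guess_threshold = 2.0 / n
    top = float(state.belief.probs.max())
    if use_generic_until_guess and top <= guess_threshold:
        key = None
    else:
        zi = state.belief.argmax()
        key = classes[zi] if classes is not None else zi
    lst = table.list_for(key)
    pos = state.traj_pos.get(key, 0)
    while pos < len(lst) and lst[pos] not in state.action_set:
        pos += 1
    state.traj_pos[key] = pos
    if pos >= len(lst):
        raise ExhaustionError("trajectory list exhausted")
    return lst[pos]


def explore_scene(
    pyramid: WaveletPyramid,
    bank: ModelBank,
    metric: str = "iglb",
    h_ref: float = 1e-4,
    *,
    policy: str = "smooth",
    predict_mode: str = "sample",
    seed: int | np.random.Generator | None = None,
    table: TrajectoryTable | None = None,
    use_generic_until_guess: bool = True,
    guess_threshold: float | None = None,
) -> ExplorationResult:
    """Sequential scene decoding with entropy stopping.

    Starts from the root-coefficient guess, then saccades under the
    chosen policy until the belief entropy drops to ``h_ref`` (nats) or
    every gaze point has been visited.  Deterministic given (pyramid,
    bank, metric, policy, h_ref, seed).
    """
    if h_ref <= 0:
        raise ValueError("h_ref must be > 0")
    if policy not in POLICY_IDS:
        raise ValueError(f"unknown policy: {policy!r}")
    eff_metric = {"sharp": "iglb_sharp", "random": "random"}.get(policy, metric)
    needs_rng = (
        policy == "random"
        or eff_metric == "random"
        or (policy in ("smooth", "sharp") and predict_mode == "sample")
    )
    rng: np.random.Generator | None = None
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    elif needs_rng:
        raise ValueError("this policy configuration requires a seed")

    if policy in ("trajectories", "generic_trajectory") and table is None:
        maps, generic = precompute_action_maps(bank)
        table = build_trajectories(maps, generic)

    belief0 = init_prior(pyramid, bank)
    state = ExplorationState.fresh(
        belief0, Belief(bank.class_prior), bank.root_log_likelihood(pyramid.root)
    )
    trace = [belief0]
    coeff_trace = [state.coefficients_read]
    trip_trace = [0]
    saccades: list[GazePoint] = []

    while True:
        if state.belief.entropy() <= h_ref:
            terminated = "threshold"
            break
        if not state.action_set:
            terminated = "exhausted"
            break
        if policy in ("smooth", "sharp", "random"):
            gaze = select_action(bank, state, eff_metric, predict_mode, rng)
        elif policy == "trajectories":
            gaze = trajectory_policy_step(
                table, state, use_generic_until_guess, guess_threshold, bank.classes
            )
        else:  # generic_trajectory
            gaze = trajectory_policy_step(
                table, state, True, float("inf"), bank.classes
            )
        field_ = read_field(pyramid, gaze, state.consumed)
        ll = field_log_likelihood_vector(field_, bank)
        new_belief = posterior_from_log(ll + state.belief.log_probs)
        state.belief_prev = state.belief
        state.belief = new_belief
        state.loglik_last = ll
        state.last_field = field_
        state.consumed.update(field_.viewpoints)
        state.action_set.discard(gaze)
        state.step += 1
        state.triplets_read += len(field_)
        state.coefficients_read += field_.n_coefficients
        saccades.append(gaze)
        trace.append(new_belief)
        coeff_trace.append(state.coefficients_read)
        trip_trace.append(state.triplets_read)

    return ExplorationResult(
        predicted=bank.classes[state.belief.argmax()],
        saccades=tuple(saccades),
        posterior_trace=tuple(trace),
        n_saccades=len(saccades),
        compression=compression_rates(state.coefficients_read, state.triplets_read),
        terminated_by=terminated,
        coefficients_read=state.coefficients_read,
        triplets_read=state.triplets_read,
        coefficients_trace=tuple(coeff_trace),
        triplets_trace=tuple(trip_trace),
        n_predictions=state.n_predictions,
    )


def threshold_readout(result: ExplorationResult, h_ref: float):
    """Replay a finished episode at a looser stopping threshold.

    The policies never consult H_ref, so an episode run at a tight
    threshold contains, along its posterior trace, the decision any
    looser threshold would have made.  Returns (predicted_index,
    n_saccades, coefficients_read, triplets_read, terminated_by).
    """
    for k, b in enumerate(result.posterior_trace):
        if b.entropy() <= h_ref:
            return (
                b.argmax(),
                k,
                result.coefficients_trace[k],
                result.triplets_trace[k],
                "threshold",
            )
    last = result.posterior_trace[-1]
    return (
        last.argmax(),
        result.n_saccades,
        result.coefficients_read,
        result.triplets_read,
        result.terminated_by,
    )


def save_action_maps(
    maps: Sequence[ActionMap], generic: ActionMap, out_dir
) -> list:
    """Serialize maps/trajectories as CSV and render PNG heat maps."""
    import csv
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    table = build_trajectories(maps, generic)
    csv_path = out / "action_maps.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "rank", "i", "j", "value"])
        for m in list(maps) + [generic]:
            lst = table.list_for(m.guess)
            label = "generic" if m.guess is None else m.guess
            for rank, (i, j) in enumerate(lst):
                w.writerow([label, rank, i, j, repr(float(m.values[i, j]))])
    written.append(csv_path)
    n = len(maps) + 1
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.6))
    for ax, m in zip(np.atleast_1d(axes), list(maps) + [generic]):
        ax.imshow(m.values, cmap="YlOrBr")
        ax.set_title("generic" if m.guess is None else str(m.guess), fontsize=8)
        ax.set_xticks([]), ax.set_yticks([])
    png_path = out / "action_maps.png"
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    written.append(png_path)
    return written
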