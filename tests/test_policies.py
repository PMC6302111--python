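"""Exploration loop, action maps and pre-processed trajectories."""

import numpy as np
import pytest

import foveate as fv
from foveate.policies import (
    ExhaustionError,
    ExplorationState,
    build_trajectories,
    precompute_action_maps,
    save_action_maps,
    select_action,
    threshold_readout,
    trajectory_policy_step,
)
from foveate.pyramid import GazePoint


@pytest.fixture(scope="module")
def episode(bank, test_pyramids):
    pyrs, _ = test_pyramids
    return fv.explore_scene(pyrs[0], bank, metric="iglb", h_ref=1e-6, seed=0)


class TestExploreScene:
    def test_inhibition_of_return(self, bank, test_pyramids):
        """No viewpoint is ever read twice across any policy."""
        pyrs, _ = test_pyramids
        for metric, policy in [("iglb", "smooth"), ("saliency", "smooth"),
                               ("iglb", "random"), ("iglb", "trajectories")]:
            res = fv.explore_scene(
                pyrs[1], bank, metric=metric, h_ref=1e-6, policy=policy, seed=1
            )
            seen = set()
            consumed = set()
            for gaze in res.saccades:
                assert gaze not in seen
                seen.add(gaze)
                f = fv.read_field(pyrs[1], gaze, consumed)
                assert not (set(f.viewpoints) & consumed)
                consumed.update(f.viewpoints)

    def test_coefficient_accounting(self, episode):
        """First saccade reads 5 triplets (15 coefficients), later ones
        1-4 triplets; the root counts as one coefficient."""
        deltas = np.diff(episode.coefficients_trace)
        assert episode.coefficients_trace[0] == 1
        assert deltas[0] == 15
        assert np.all((deltas[1:] >= 3) & (deltas[1:] <= 12))
        assert episode.triplets_trace[-1] == episode.triplets_read
        assert (
            episode.coefficients_read == 1 + 3 * episode.triplets_read
        )

    def test_determinism(self, bank, test_pyramids):
        pyrs, _ = test_pyramids
        a = fv.explore_scene(pyrs[2], bank, metric="ci", h_ref=1e-4, seed=5)
        b = fv.explore_scene(pyrs[2], bank, metric="ci", h_ref=1e-4, seed=5)
        assert a.saccades == b.saccades
        assert a.predicted == b.predicted
        assert a.compression == b.compression

    def test_threshold_met_at_start(self, bank, test_pyramids):
        pyrs, _ = test_pyramids
        res = fv.explore_scene(pyrs[0], bank, h_ref=np.log(10) + 0.01, seed=0)
        assert res.n_saccades == 0
        assert res.terminated_by == "threshold"
        assert len(res.posterior_trace) == 1

    def test_exhaustion_on_ambiguous_scene(self, bank):
        """A blank scene never resolves: the loop visits all 256 gazes
        and consumes all 341 triplets."""
        pyr = fv.haar_decompose(np.zeros((32, 32)))
        res = fv.explore_scene(
            pyr, bank, metric="iglb", h_ref=1e-9, predict_mode="mode", seed=0
        )
        assert res.terminated_by == "exhausted"
        assert res.n_saccades == 256
        assert res.triplets_read == 341
        assert res.compression[0] == fv.compression_rates(1 + 3 * 341, 341)[0]

    def test_posterior_trace_length(self, episode):
        assert len(episode.posterior_trace) == episode.n_saccades + 1

    def test_seed_required_when_stochastic(self, bank, test_pyramids):
        pyrs, _ = test_pyramids
        with pytest.raises(ValueError):
            fv.explore_scene(pyrs[0], bank, metric="iglb", h_ref=1e-4)
        # mode prediction is deterministic: no seed needed
        res = fv.explore_scene(
            pyrs[0], bank, metric="iglb", h_ref=1e-2, predict_mode="mode"
        )
        assert res.n_saccades >= 0

    def test_threshold_readout_consistency(self, bank, test_pyramids):
        """Replaying a tight episode at a looser threshold matches a
        fresh run at that threshold (policies never consult H_ref)."""
        pyrs, _ = test_pyramids
        tight = fv.explore_scene(pyrs[4], bank, metric="iglb", h_ref=1e-5, seed=9)
        loose = fv.explore_scene(pyrs[4], bank, metric="iglb", h_ref=1e-2, seed=9)
        zi, n_sac, n_coeff, n_trip, term = threshold_readout(tight, 1e-2)
        assert bank.classes[zi] == loose.predicted
        assert n_sac == loose.n_saccades
        assert n_coeff == loose.coefficients_read


class TestSelectAction:
    def test_random_reproducible(self, bank, test_pyramids):
        pyrs, _ = test_pyramids
        state = _fresh_state(pyrs[0], bank)
        a = select_action(bank, state, "random", rng=3)
        b = select_action(bank, state, "random", rng=3)
        assert a == b

    def test_empty_action_set(self, bank, test_pyramids):
        pyrs, _ = test_pyramids
        state = _fresh_state(pyrs[0], bank)
        state.action_set.clear()
        with pytest.raises(ExhaustionError):
            select_action(bank, state, "iglb", "mode")

    def test_single_class_follows_action_map(self, glyph_data):
        """With |Z| = 1 and mode prediction, iglb selection equals the
        top of that class's action map."""
        tr_x, tr_y, _, _ = glyph_data
        sel = tr_y == tr_y[0]
        bank1 = fv.fit_model_bank(list(tr_x[sel][:20]), tr_y[sel][:20])
        maps, generic = precompute_action_maps(bank1)
        table = build_trajectories(maps, generic)
        pyr = fv.haar_decompose(tr_x[sel][0])
        state = _fresh_state(pyr, bank1)
        got = select_action(bank1, state, "iglb", "mode")
        assert got == table.per_class[bank1.classes[0]][0]

    def test_infomax_matches_entropy_minimizer(self, toy_worlds):
        """Predicted Infomax selection equals the brute-force expected
        posterior entropy minimizer (full enumeration)."""
        rng = np.random.default_rng(17)
        for world in toy_worlds[:10]:
            q = fv.Belief(rng.dirichlet(np.ones(world.n_states)))
            scores = fv.expected_metric_scores(world.emission, q, "infomax")
            # independent oracle: minimize E[H(posterior)] directly
            exp_h = np.empty(world.n_actions)
            for u in range(world.n_actions):
                h = 0.0
                for x in range(world.n_symbols):
                    p_x = float(world.emission[:, u, x] @ q.probs)
                    if p_x == 0:
                        continue
                    post = world.emission[:, u, x] * q.probs
                    post = post / post.sum()
                    nz = post > 0
                    h -= p_x * float((post[nz] * np.log(post[nz])).sum())
                exp_h[u] = h
            assert int(np.argmax(scores)) == int(np.argmin(exp_h))


class TestActionMaps:
    def test_single_class_map_is_zero(self, glyph_data):
        tr_x, tr_y, _, _ = glyph_data
        sel = tr_y == tr_y[0]
        bank1 = fv.fit_model_bank(list(tr_x[sel][:20]), tr_y[sel][:20])
        maps, generic = precompute_action_maps(bank1)
        assert len(maps) == 1
        assert np.allclose(maps[0].values, 0.0, atol=1e-12)
        assert np.allclose(generic.values, 0.0, atol=1e-12)

    def test_identical_classes_identical_maps(self, glyph_data):
        tr_x, tr_y, _, _ = glyph_data
        sel = np.nonzero(tr_y == tr_y[0])[0][:12]
        imgs = list(tr_x[sel]) + list(tr_x[sel])
        labels = [0] * 12 + [1] * 12
        maps, _ = precompute_action_maps(fv.fit_model_bank(imgs, labels))
        assert np.allclose(maps[0].values, maps[1].values)

    def test_generic_is_uniform_average(self, bank):
        maps, generic = precompute_action_maps(bank)
        assert np.allclose(
            generic.values, np.mean([m.values for m in maps], axis=0)
        )

    def test_serialization(self, bank, tmp_path):
        maps, generic = precompute_action_maps(bank)
        written = save_action_maps(maps, generic, tmp_path)
        assert (tmp_path / "action_maps.csv").exists()
        assert (tmp_path / "action_maps.png").exists()
        header = (tmp_path / "action_maps.csv").read_text().splitlines()[0]
        assert header == "class,rank,i,j,value"


class TestTrajectories:
    def test_lists_are_permutations(self, bank):
        maps, generic = precompute_action_maps(bank)
        table = build_trajectories(maps, generic)
        full = {GazePoint(i, j) for i in range(16) for j in range(16)}
        for lst in list(table.per_class.values()) + [table.generic]:
            assert len(lst) == 256 and set(lst) == full

    def test_constant_map_row_major(self):
        m = fv.ActionMap(guess=0, values=np.zeros((16, 16)))
        table = build_trajectories([m], fv.ActionMap(None, np.zeros((16, 16))))
        assert table.per_class[0][:3] == (
            GazePoint(0, 0),
            GazePoint(0, 1),
            GazePoint(0, 2),
        )

    def test_unique_maximum_first(self):
        vals = np.zeros((16, 16))
        vals[5, 3] = 1.0
        table = build_trajectories([fv.ActionMap(0, vals)], fv.ActionMap(None, vals))
        assert table.per_class[0][0] == GazePoint(5, 3)

    def test_step_semantics_and_guess_switch(self, bank):
        maps, generic = precompute_action_maps(bank)
        table = build_trajectories(maps, generic)
        n = bank.n_classes
        state = ExplorationState.fresh(
            _peaked_belief(n, 0), fv.Belief.uniform(n), np.zeros(n)
        )
        first = trajectory_policy_step(table, state, classes=bank.classes)
        assert first == table.per_class[bank.classes[0]][0]
        state.action_set.discard(first)
        # guess flips to class 1: next gaze comes from the new list
        state.belief = _peaked_belief(n, 1)
        nxt = trajectory_policy_step(table, state, classes=bank.classes)
        lst = table.per_class[bank.classes[1]]
        expect = lst[0] if lst[0] != first else lst[1]
        assert nxt == expect

    def test_generic_until_guess(self, bank):
        maps, generic = precompute_action_maps(bank)
        table = build_trajectories(maps, generic)
        n = bank.n_classes
        state = ExplorationState.fresh(
            fv.Belief.uniform(n), fv.Belief.uniform(n), np.zeros(n)
        )
        got = trajectory_policy_step(table, state, classes=bank.classes)
        assert got == table.generic[0]

    def test_exhaustion(self, bank):
        maps, generic = precompute_action_maps(bank)
        table = build_trajectories(maps, generic)
        n = bank.n_classes
        state = ExplorationState.fresh(
            fv.Belief.uniform(n), fv.Belief.uniform(n), np.zeros(n)
        )
        state.action_set.clear()
        with pytest.raises(ExhaustionError):
            trajectory_policy_step(table, state, classes=bank.classes)

    def test_selection_cost_independent_of_model_size(self, bank, test_pyramids):
        """Trajectory readout performs no emission-model predictions,
        unlike smooth selection whose cost scales with |U| x |Z|."""
        pyrs, _ = test_pyramids
        smooth = fv.explore_scene(pyrs[0], bank, metric="iglb", h_ref=1e-4, seed=0)
        traj = fv.explore_scene(
            pyrs[0], bank, metric="iglb", h_ref=1e-4, policy="trajectories", seed=0
        )
        sharp = fv.explore_scene(
            pyrs[0], bank, metric="iglb", h_ref=1e-4, policy="sharp", seed=0
        )
        assert traj.n_predictions == 0
        assert smooth.n_predictions >= 256 * bank.n_classes  # first step alone
        # sharp predicts for a single class per candidate
        assert sharp.n_predictions <= smooth.n_predictions / (bank.n_classes - 1)


def _fresh_state(pyr, bank) -> ExplorationState:
    return ExplorationState.fresh(
        fv.init_prior(pyr, bank),
        fv.Belief(bank.class_prior),
        bank.root_log_likelihood(pyr.root),
    )


def _peaked_belief(n, idx, top=0.9):
    p = np.full(n, (1 - top) / (n - 1))
    p[idx] = top
    return fv.Belief(p)
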