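"""Metropolis-Hastings sampler: acceptance rule, proposals, trajectories."""

import math

import numpy as np
import pytest

from evoscreen import (
    EvolutionConfig,
    Mutation,
    PottsModel,
    VariantGenotype,
    extract_top_sequences,
    metropolis_accept,
    propose_move,
    run_evolution,
    run_trajectory,
)
from evoscreen.evolve import _MoveTable, _propose_encoded

from conftest import random_model


def zero_model(L=4, q=3):
    alphabet = "ACDEFGHIK"[:q]
    return PottsModel(
        h=np.zeros((L, q)),
        J=np.zeros((L, L, q, q)),
        wt_sequence=alphabet[0] * L,
        alphabet=alphabet,
    )


class TestMetropolisAccept:
    def test_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, 0.03, rng) for _ in range(100))

    def test_large_positive_always_accepted(self, rng):
        for T in (0.3, 0.03, 0.003):
            assert metropolis_accept(5.0, T, rng)

    def test_empirical_rate_matches_closed_form(self, rng):
        # delta = -T  ->  acceptance probability e^-1
        n = 100_000
        T = 0.07
        accepted = sum(metropolis_accept(-T, T, rng) for _ in range(n))
        p = math.exp(-1)
        se = math.sqrt(p * (1 - p) / n)
        assert accepted / n == pytest.approx(p, abs=3 * se)

    def test_deep_negative_never_accepted(self, rng):
        assert not any(metropolis_accept(-100.0, 0.03, rng) for _ in range(100))

    def test_non_finite_delta_rejected(self, rng):
        with pytest.raises(ValueError, match="non-finite"):
            metropolis_accept(float("nan"), 0.03, rng)

    def test_non_positive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(0.1, 0.0, rng)


class TestProposeMove:
    def test_zero_trust_radius_never_leaves_wild_type(self, rng):
        m = zero_model()
        cfg = EvolutionConfig(n_trajectories=1, n_steps=5, trust_radius=0, temperature=1.0)
        wt = VariantGenotype(())
        for _ in range(50):
            assert propose_move(m, wt, cfg, rng) == wt

    def test_boundary_state_stays_within_radius(self, rng):
        m = random_model(L=8, q=4, seed=3)
        cfg = EvolutionConfig(n_trajectories=1, n_steps=5, trust_radius=2, temperature=1.0)
        wt = m.wt_encoded()
        table = _MoveTable(m, cfg)
        state = wt.copy()
        # place the state exactly at the trust-radius boundary
        for i in (0, 3):
            state[i] = (state[i] + 1) % m.q
        for _ in range(10_000):
            move = _propose_encoded(state, wt, table, cfg.trust_radius, rng)
            assert move is not None
            i, b = move
            cand = state.copy()
            cand[i] = b
            assert (cand != wt).sum() <= cfg.trust_radius
            assert i in (0, 3)  # only already-mutated positions at the boundary

    def test_explicit_allowed_moves_closure(self, rng):
        m = random_model(L=10, q=4, seed=5)
        wt = m.wt_sequence
        allowed = tuple(
            Mutation(p, wt[p - 1], next(s for s in m.alphabet if s != wt[p - 1]))
            for p in (2, 5, 7, 9)
        )
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=5, trust_radius=3, temperature=1.0,
            allowed_moves=allowed,
        )
        state = VariantGenotype((allowed[0],))
        seen = set()
        for _ in range(10_000):
            prop = propose_move(m, state, cfg, rng)
            diff = set(prop.mutations) ^ set(state.mutations)
            seen.add(frozenset(d.label for d in diff))
        # closure: introduce one of the other three moves, or revert the first
        expected = {frozenset({mu.label}) for mu in allowed[1:]}
        expected.add(frozenset({allowed[0].label}))
        assert seen == expected

    def test_empty_allowed_moves_rejected(self):
        with pytest.raises(ValueError, match="allowed_moves"):
            EvolutionConfig(n_trajectories=1, n_steps=1, allowed_moves=())

    def test_state_outside_radius_rejected(self, rng):
        m = random_model(L=6, q=4, seed=2)
        cfg = EvolutionConfig(n_trajectories=1, n_steps=1, trust_radius=1, temperature=1.0)
        muts = []
        for p in (1, 2):
            wt = m.wt_sequence[p - 1]
            muts.append(Mutation(p, wt, next(s for s in m.alphabet if s != wt)))
        with pytest.raises(ValueError, match="trust radius"):
            propose_move(m, VariantGenotype(tuple(muts)), cfg, rng)


class TestRunTrajectory:
    def test_flat_landscape_accepts_everything(self):
        m = zero_model(L=5, q=3)
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=200, trust_radius=5, temperature=0.1, rng_seed=0
        )
        rec = run_trajectory(m, cfg)
        assert rec.accepted.all()
        assert rec.n_steps == 200
        assert (rec.scores == 0).all()

    def test_record_shape_and_start(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=50, trust_radius=2, temperature=0.1, rng_seed=7
        )
        rec = run_trajectory(small_model, cfg)
        assert rec.states.shape == (51, small_model.L)
        np.testing.assert_array_equal(rec.states[0], small_model.wt_encoded())
        assert rec.scores[0] == 0.0
        assert rec.best_score == rec.scores.max()

    def test_trust_radius_containment(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=300, trust_radius=2, temperature=1.0, rng_seed=3
        )
        rec = run_trajectory(small_model, cfg)
        assert rec.hamming_distances().max() <= 2

    def test_scores_consistent_with_energy(self, small_model):
        from evoscreen import potts_energy

        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=100, trust_radius=3, temperature=0.5, rng_seed=11
        )
        rec = run_trajectory(small_model, cfg)
        wt_e = potts_energy(small_model, small_model.wt_sequence)
        for k in (10, 50, 100):
            direct = potts_energy(small_model, rec.states[k]) - wt_e
            assert rec.scores[k] == pytest.approx(direct, abs=1e-9)

    def test_greedy_limit_accepts_only_improvements(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=300, trust_radius=3, temperature=1e-9, rng_seed=5
        )
        rec = run_trajectory(small_model, cfg)
        deltas = np.diff(rec.scores)[rec.accepted]
        assert (deltas >= -1e-12).all()

    def test_greedy_limit_finds_single_planted_mutation(self):
        # one strongly beneficial exchange; near-zero temperature chains
        # should land on it almost surely
        L, q = 8, 4
        m = zero_model(L=L, q=q)
        m.h[4, 2] = 2.0  # planted: position 5 -> symbol index 2
        hits = 0
        for seed in range(50):
            cfg = EvolutionConfig(
                n_trajectories=1, n_steps=500, trust_radius=2,
                temperature=1e-9, rng_seed=seed,
            )
            rec = run_trajectory(m, cfg)
            hits += rec.best_state[4] == 2
        assert hits >= 49


class TestRunEvolution:
    def test_single_trajectory_reduces_to_run_trajectory(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=30, trust_radius=2, temperature=0.1, rng_seed=9
        )
        [rec] = run_evolution(small_model, cfg)
        seed = np.random.SeedSequence(cfg.rng_seed).spawn(1)[0]
        direct = run_trajectory(small_model, cfg, rng=np.random.default_rng(seed))
        np.testing.assert_array_equal(rec.states, direct.states)
        np.testing.assert_array_equal(rec.accepted, direct.accepted)

    def test_same_seed_gives_identical_records(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=5, n_steps=40, trust_radius=2, temperature=0.1, rng_seed=21
        )
        a = run_evolution(small_model, cfg)
        b = run_evolution(small_model, cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.states, rb.states)
            np.testing.assert_array_equal(ra.scores, rb.scores)

    def test_parallel_matches_serial(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=4, n_steps=30, trust_radius=2, temperature=0.1, rng_seed=13
        )
        serial = run_evolution(small_model, cfg, n_jobs=1)
        parallel = run_evolution(small_model, cfg, n_jobs=2)
        for ra, rb in zip(serial, parallel):
            np.testing.assert_array_equal(ra.states, rb.states)
            np.testing.assert_array_equal(ra.scores, rb.scores)

    def test_trajectory_count_does_not_perturb_early_chains(self, small_model):
        cfg5 = EvolutionConfig(
            n_trajectories=5, n_steps=30, trust_radius=2, temperature=0.1, rng_seed=2
        )
        cfg3 = EvolutionConfig(
            n_trajectories=3, n_steps=30, trust_radius=2, temperature=0.1, rng_seed=2
        )
        five = run_evolution(small_model, cfg5)
        three = run_evolution(small_model, cfg3)
        for ra, rb in zip(three, five):
            np.testing.assert_array_equal(ra.states, rb.states)


class TestExtractTopSequences:
    def test_single_trajectory_best_is_rank_one(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=100, trust_radius=2, temperature=0.3, rng_seed=4
        )
        recs = run_evolution(small_model, cfg)
        tops = extract_top_sequences(small_model, recs, n_top=1)
        assert tops[0].score == pytest.approx(recs[0].best_score)
        assert tops[0].sequence == small_model.decode(recs[0].best_state)

    def test_global_top_matches_exhaustive_ranking(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=3, n_steps=80, trust_radius=2, temperature=0.5, rng_seed=8
        )
        recs = run_evolution(small_model, cfg)
        tops = extract_top_sequences(small_model, recs, n_top=10, mode="global-top")
        # oracle: enumerate every visited state across all records
        best = {}
        for rec in recs:
            for state, score in zip(rec.states, rec.scores):
                best.setdefault(tuple(state), float(score))
        oracle = sorted(best.values(), reverse=True)[:10]
        assert [t.score for t in tops] == pytest.approx(oracle)

    def test_equal_scores_tie_broken_deterministically(self):
        m = zero_model(L=3, q=3)
        cfg = EvolutionConfig(
            n_trajectories=2, n_steps=20, trust_radius=1, temperature=1.0, rng_seed=6
        )
        recs = run_evolution(m, cfg)
        t1 = extract_top_sequences(m, recs, n_top=5)
        t2 = extract_top_sequences(m, recs, n_top=5)
        assert [t.sequence for t in t1] == [t.sequence for t in t2]
        # flat landscape: all scores equal, first-visited order decides
        assert t1[0].trajectory_index <= t1[-1].trajectory_index

    def test_warns_when_fewer_distinct_states(self, small_model):
        cfg = EvolutionConfig(
            n_trajectories=1, n_steps=5, trust_radius=1, temperature=0.1, rng_seed=1
        )
        recs = run_evolution(small_model, cfg)
        with pytest.warns(UserWarning, match="distinct"):
            extract_top_sequences(small_model, recs, n_top=1000)
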