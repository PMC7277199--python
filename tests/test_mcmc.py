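"""Metropolis-Hastings sampler: proposals, acceptance rule, chains."""

import numpy as np
import pytest

from pansimc.mcmc import (
    Chain,
    ChainConfig,
    acceptance_rate,
    discard_burnin,
    mh_step,
    propose,
    run_chain,
    suggested_proposal_scale,
)


def std_normal_2d(x):
    return float(np.exp(-0.5 * np.dot(x, x)))


class TestPropose:
    def test_tiny_scale_limit_stays_at_state(self, rng):
        state = np.array([3.0, -2.0])
        cand = propose(state, 1e-300, rng)
        assert np.allclose(cand, state)

    def test_unit_scale_component_variances(self, rng):
        draws = np.array([propose(np.zeros(2), 1.0, rng) for _ in range(100_000)])
        assert draws.var(axis=0) == pytest.approx([1.0, 1.0], abs=0.02)
        assert abs(np.cov(draws.T)[0, 1]) < 0.02

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            propose(np.zeros(2), 0.0, rng)


class TestMhStep:
    def test_uphill_moves_always_accepted(self, rng):
        nxt, acc, _ = mh_step(np.array([2.0, 0.0]), np.zeros(2), std_normal_2d, rng)
        assert acc and np.allclose(nxt, 0.0)

    def test_zero_density_candidate_never_accepted(self, rng):
        target = lambda x: 1.0 if x[0] < 0 else 0.0  # noqa: E731
        cur = np.array([-1.0, 0.0])
        for _ in range(50):
            nxt, acc, _ = mh_step(cur, np.array([1.0, 0.0]), target, rng)
            assert not acc and np.allclose(nxt, cur)

    def test_zero_density_current_errors(self, rng):
        with pytest.raises(ValueError, match="zero at the current"):
            mh_step(np.zeros(2), np.ones(2), lambda x: 0.0, rng)

    def test_fixed_ratio_acceptance_frequency(self, rng):
        """With J(candidate)/J(current) pinned at 0.5 the empirical acceptance
        frequency is 0.5 within 3 binomial standard errors."""
        target = lambda x: 0.5 if x[0] > 0 else 1.0  # noqa: E731
        n = 100_000
        hits = 0
        cur = np.array([-1.0, 0.0])
        cand = np.array([1.0, 0.0])
        for _ in range(n):
            _, acc, _ = mh_step(cur, cand, target, rng)
            hits += acc
        se = np.sqrt(0.25 / n)
        assert hits / n == pytest.approx(0.5, abs=3 * se)


class TestRunChain:
    def test_gaussian_target_moment_recovery(self):
        cfg = ChainConfig(iterations=50_000, proposal_scale=1.0, seed=3,
                          initial_state=(0.0, 0.0))
        chain = run_chain(std_normal_2d, cfg)
        kept = discard_burnin(chain)
        assert kept.mean(axis=0) == pytest.approx([0.0, 0.0], abs=0.05)
        assert kept.var(axis=0) == pytest.approx([1.0, 1.0], abs=0.1)
        assert abs(np.corrcoef(kept.T)[0, 1]) < 0.05

    def test_same_seed_bitwise_identical(self):
        cfg = ChainConfig(iterations=500, seed=11, initial_state=(0.1, 0.2))
        c1 = run_chain(std_normal_2d, cfg)
        c2 = run_chain(std_normal_2d, cfg)
        assert np.array_equal(c1.states, c2.states)
        assert np.array_equal(c1.accepted, c2.accepted)

    def test_zero_iterations_gives_initial_state_only(self):
        cfg = ChainConfig(iterations=0, burnin=0, seed=1, initial_state=(1.0, 2.0))
        chain = run_chain(std_normal_2d, cfg)
        assert chain.states.shape == (1, 2)
        assert np.allclose(chain.states[0], [1.0, 2.0])

    def test_target_scaling_leaves_chain_invariant(self):
        """Only density ratios enter the acceptance rule: scaling the target
        by any positive constant yields the identical chain."""
        cfg = ChainConfig(iterations=2_000, seed=7, initial_state=(0.5, -0.5))
        c1 = run_chain(std_normal_2d, cfg)
        c2 = run_chain(lambda x: 37.2 * std_normal_2d(x), cfg)
        assert np.array_equal(c1.states, c2.states)

    def test_random_individual_start_is_a_respondent_pair(self):
        scores = np.array([[3.0, 10.0], [5.0, 20.0], [8.0, 30.0]])
        cfg = ChainConfig(iterations=0, burnin=0, seed=5)
        chain = run_chain(std_normal_2d, cfg, scores=scores / 10.0)
        assert any(np.allclose(chain.states[0], row) for row in scores / 10.0)

    def test_random_individual_without_scores_errors(self):
        with pytest.raises(ValueError, match="scores"):
            run_chain(std_normal_2d, ChainConfig(iterations=10, seed=0))

    def test_zero_density_start_errors(self):
        target = lambda x: 1.0 if x[0] < 0 else 0.0  # noqa: E731
        cfg = ChainConfig(iterations=10, seed=0, initial_state=(1.0, 0.0))
        with pytest.raises(ValueError, match="zero at the initial state"):
            run_chain(target, cfg)

    def test_chain_never_visits_zero_density_state(self):
        target = lambda x: 1.0 if abs(x[0]) < 2 and abs(x[1]) < 2 else 0.0  # noqa: E731
        cfg = ChainConfig(iterations=2_000, seed=2, initial_state=(0.0, 0.0))
        chain = run_chain(target, cfg)
        assert all(target(s) > 0 for s in chain.states)

    def test_states_follow_accept_reject_contract(self):
        cfg = ChainConfig(iterations=1_000, seed=9, initial_state=(0.0, 0.0))
        chain = run_chain(std_normal_2d, cfg)
        moved = ~np.all(chain.states[1:] == chain.states[:-1], axis=1)
        # every rejected step repeats the state; every move was an acceptance
        assert not np.any(moved & ~chain.accepted)


class TestDiscreteOracle:
    @pytest.mark.parametrize("r", [0.2, 1.0, 5.0])
    def test_two_state_occupancy_matches_stationary_distribution(self, r, rng):
        """Driving the accept/reject rule between two fixed states with
        density ratio r must occupy them as (1/(1+r), r/(1+r))."""
        s0, s1 = np.array([0.0, 0.0]), np.array([1.0, 0.0])
        target = lambda x: r if x[0] > 0.5 else 1.0  # noqa: E731
        n = 20_000
        cur = s0
        occ1 = 0
        for _ in range(n):
            cand = s1 if cur[0] < 0.5 else s0
            cur, _, _ = mh_step(cur, cand, target, rng)
            occ1 += cur[0] > 0.5
        p = r / (1 + r)
        se = np.sqrt(p * (1 - p) / n)
        assert occ1 / n == pytest.approx(p, abs=3 * se)


class TestBurninAndDiagnostics:
    def test_burnin_discard_counts(self):
        states = np.arange(202.0).reshape(101, 2)
        chain = Chain(states=states, accepted=np.ones(100, bool), burnin=10, seed=0)
        kept = discard_burnin(chain)
        assert kept.shape == (91, 2)
        assert np.array_equal(kept, states[10:])

    def test_zero_burnin_returns_full_chain(self):
        states = np.zeros((5, 2))
        chain = Chain(states=states, accepted=np.zeros(4, bool), burnin=0, seed=0)
        assert discard_burnin(chain).shape == (5, 2)

    def test_burnin_exceeding_length_errors(self):
        chain = Chain(states=np.zeros((5, 2)), accepted=np.zeros(4, bool), burnin=5, seed=0)
        with pytest.raises(ValueError):
            discard_burnin(chain)

    def test_acceptance_rate_extremes(self):
        c_all = Chain(np.zeros((4, 2)), np.ones(3, bool), 0, 0)
        c_none = Chain(np.zeros((4, 2)), np.zeros(3, bool), 0, 0)
        assert acceptance_rate(c_all) == 1.0
        assert acceptance_rate(c_none) == 0.0
        with pytest.raises(ValueError):
            acceptance_rate(Chain(np.zeros((1, 2)), np.zeros(0, bool), 0, 0))

    def test_flat_target_accepts_everything(self):
        cfg = ChainConfig(iterations=200, seed=4, initial_state=(0.0, 0.0))
        chain = run_chain(lambda x: 1.0, cfg)
        assert acceptance_rate(chain) == 1.0

    def test_default_burnin_is_tenth_of_iterations(self):
        assert ChainConfig(iterations=20_000).burnin == 2_000

    def test_chain_csv_dump_columns(self, tmp_path):
        cfg = ChainConfig(iterations=50, seed=1, initial_state=(0.0, 0.0))
        chain = run_chain(std_normal_2d, cfg)
        df = chain.to_dataframe()
        assert list(df.columns) == ["iter", "x1", "x2", "accepted", "is_burnin"]
        assert df["is_burnin"].sum() == chain.burnin
        chain.to_csv(tmp_path / "chain.csv")
        assert (tmp_path / "chain.csv").exists()


def test_suggested_scale_tracks_score_spread(rng):
    pts = rng.normal(size=(500, 2)) * [4.0, 8.0]
    scale = suggested_proposal_scale(pts)
    assert scale == pytest.approx(2.38 / np.sqrt(2) * 6.0, rel=0.15)
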