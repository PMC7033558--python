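"""Single-simulator tests: quit-timer law, absorption oracle, censoring."""

import numpy as np
import pytest

from handrace.diffusion import (
    ACCEPT,
    QUIT,
    REJECT,
    ConfigError,
    SimulatorParams,
    absorption_oracle,
    draw_quit_time,
    draw_quit_times,
    quit_lognormal_params,
    simulate_passage,
    simulate_passages,
)

NO_QUIT = 1e6  # effectively disables the quit-timer


def uncensored(**kw) -> SimulatorParams:
    return SimulatorParams(quit_mean=NO_QUIT, **kw)


class TestQuitTimer:
    def test_moment_matched_mean_and_sd(self, rng):
        """Arithmetic mean 1.6 s and SD 1 s survive the log-normal mapping."""
        p = SimulatorParams(quit_mean=1.6, quit_sigma=1.0)
        draws = draw_quit_times(p, 100_000, rng)
        assert np.all(draws > 0)
        se_mean = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.6) < 3 * se_mean
        # SD of the SD estimator, conservatively from the fourth moment
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_sd = np.sqrt(max(m4 - draws.var() ** 2, 0) / draws.size) / (2 * draws.std())
        assert abs(draws.std() - 1.0) < 4 * se_sd

    def test_analytic_lognormal_parameters(self):
        """Moment matching solved in closed form: mean/SD of exp(N(mu, s))."""
        p = SimulatorParams(quit_mean=1.6, quit_sigma=1.0)
        mu, sigma = quit_lognormal_params(p)
        mean = np.exp(mu + sigma**2 / 2)
        sd = mean * np.sqrt(np.expm1(sigma**2))
        assert mean == pytest.approx(1.6, abs=1e-12)
        assert sd == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_sigma_collapses_to_mean(self, rng):
        p = SimulatorParams(quit_mean=1.6, quit_sigma=1e-6)
        draws = draw_quit_times(p, 1000, rng)
        assert np.allclose(draws, 1.6, atol=1e-4)

    def test_log_space_parameterisation(self, rng):
        p = SimulatorParams(quit_mean=1.6, quit_sigma=0.5, quit_parameterization="log")
        draws = np.log(draw_quit_times(p, 50_000, rng))
        assert draws.mean() == pytest.approx(np.log(1.6), abs=0.01)
        assert draws.std() == pytest.approx(0.5, abs=0.01)

    def test_scalar_draw(self, rng):
        assert draw_quit_time(SimulatorParams(), rng) > 0


@pytest.mark.parametrize(
    "bad",
    [
        dict(quit_mean=0.0),
        dict(quit_sigma=-1.0),
        dict(threshold=0.0),
        dict(start_bias=0.2, threshold=0.1),  # |z| >= separation/2
        dict(nondecision_time=-0.1),
        dict(noise_coef=0.0),
        dict(dt=0.0),
        dict(dt=2.0, quit_mean=1.6),  # timer unresolvable
        dict(quit_parameterization="base10"),
        dict(threshold_convention="diagonal"),
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(ConfigError):
        SimulatorParams(**bad)


class TestAbsorptionOracle:
    def test_zero_drift_closed_form(self):
        p = uncensored(drift_rate=0.0, start_bias=0.0, threshold=0.17, threshold_convention="full")
        prob, mean_t = absorption_oracle(p, +1)
        a = 0.17
        assert prob == pytest.approx(0.5)
        assert mean_t == pytest.approx((a / 2) * (a - a / 2) / 0.1**2)

    def test_opposite_biases_sum_to_one_at_zero_drift(self):
        up = absorption_oracle(uncensored(drift_rate=0.0, start_bias=0.02), +1)[0]
        dn = absorption_oracle(uncensored(drift_rate=0.0, start_bias=-0.02), +1)[0]
        assert up + dn == pytest.approx(1.0, abs=1e-12)

    def test_drift_limit_is_continuous(self):
        near = absorption_oracle(uncensored(drift_rate=1e-14), +1)
        zero = absorption_oracle(uncensored(drift_rate=0.0), +1)
        assert near[0] == pytest.approx(zero[0], abs=1e-9)
        assert near[1] == pytest.approx(zero[1], rel=1e-6)

    def test_half_vs_full_convention(self):
        """threshold=0.1 under 'half' equals threshold=0.2 under 'full'."""
        half = absorption_oracle(uncensored(threshold=0.1, threshold_convention="half"), +1)
        full = absorption_oracle(uncensored(threshold=0.2, threshold_convention="full"), +1)
        assert half == pytest.approx(full)


class TestSimulatedPassages:
    def test_matches_oracle_without_quit_timer(self, rng):
        """Published control parameters, uncensored: P(accept) and mean
        decision time agree with the Wiener closed forms."""
        p = uncensored(
            drift_rate=0.1, threshold=0.17, start_bias=0.0, noise_coef=0.1,
            threshold_convention="full",
        )
        n = 30_000
        ev, t = simulate_passages(p, +1, n, rng)
        p_or, t_or = absorption_oracle(p, +1)
        p_hat = np.mean(ev == ACCEPT)
        assert abs(p_hat - p_or) < 3 * np.sqrt(p_or * (1 - p_or) / n)
        assert abs(t.mean() - t_or) < 3 * t.std() / np.sqrt(n)

    def test_matches_oracle_with_bias_and_negative_drift(self, rng):
        p = uncensored(drift_rate=0.08, threshold=0.12, start_bias=0.01, noise_coef=0.11)
        n = 20_000
        ev, t = simulate_passages(p, -1, n, rng)
        p_or, t_or = absorption_oracle(p, -1)
        p_hat = np.mean(ev == ACCEPT)
        assert abs(p_hat - p_or) < 3 * np.sqrt(p_or * (1 - p_or) / n)
        assert abs(t.mean() - t_or) < 3 * t.std() / np.sqrt(n)

    def test_symmetric_process_splits_evenly(self, rng):
        p = uncensored(drift_rate=0.0, start_bias=0.0)
        n = 20_000
        ev, _ = simulate_passages(p, +1, n, rng)
        assert abs(np.mean(ev == ACCEPT) - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_congenital_parameters_produce_quits(self, rng):
        """At the published congenital parameters a nonzero fraction of
        trials terminates by quitting."""
        p = SimulatorParams(drift_rate=0.1, threshold=0.138, start_bias=0.006,
                            quit_mean=1.6, quit_sigma=1.0)
        ev, t = simulate_passages(p, +1, 5000, rng)
        assert np.mean(ev == QUIT) > 0.01
        assert np.all(t > 0)

    def test_quit_decision_time_equals_drawn_quit_time(self):
        """Replaying the quit-timer stream shows quit trials carry their
        own drawn quit-time as the decision time."""
        p = SimulatorParams(quit_mean=0.4, quit_sigma=0.3)
        ev, t = simulate_passages(p, +1, 2000, np.random.default_rng(77))
        drawn = draw_quit_times(p, 2000, np.random.default_rng(77))
        quits = ev == QUIT
        assert quits.any()
        assert np.allclose(t[quits], drawn[quits])
        # and every trial ends no later than its quit-time plus one step
        assert np.all(t <= drawn + p.dt + 1e-12)

    def test_censoring_monotonicity(self):
        """Shrinking the quit deadline never increases the accept fraction."""
        fracs = []
        for qm in (3.2, 1.6, 0.8, 0.4, 0.2):
            p = SimulatorParams(quit_mean=qm, quit_sigma=min(1.0, qm / 2))
            ev, _ = simulate_passages(p, +1, 8000, np.random.default_rng(5))
            fracs.append(np.mean(ev == ACCEPT))
        assert all(a >= b - 0.01 for a, b in zip(fracs, fracs[1:]))

    def test_step_size_convergence(self):
        """Accept probability at dt = 4 ms and dt = 1 ms agree within
        pooled Monte-Carlo error (bridge-corrected crossings)."""
        n = 20_000
        ps = []
        for dt in (0.004, 0.001):
            p = SimulatorParams(dt=dt)
            ev, _ = simulate_passages(p, +1, n, np.random.default_rng(11))
            ps.append(np.mean(ev == ACCEPT))
        pooled_se = np.sqrt(2 * ps[0] * (1 - ps[0]) / n)
        assert abs(ps[0] - ps[1]) < 3 * pooled_se

    def test_determinism(self):
        p = SimulatorParams()
        ev1, t1 = simulate_passages(p, +1, 500, np.random.default_rng(3))
        ev2, t2 = simulate_passages(p, +1, 500, np.random.default_rng(3))
        assert np.array_equal(ev1, ev2) and np.array_equal(t1, t2)

    def test_single_trial_wrapper(self, rng):
        res = simulate_passage(SimulatorParams(), +1, rng)
        assert res.event in ("accept", "reject", "quit")
        assert res.decision_time > 0

    def test_invalid_drift_sign(self, rng):
        with pytest.raises(ValueError):
            simulate_passages(SimulatorParams(), 0, 10, rng)


def test_yaml_round_trip(tmp_path):
    p = SimulatorParams(drift_rate=0.07, threshold=0.15, start_bias=-0.004)
    path = tmp_path / "sim.yaml"
    p.to_yaml(path)
    assert SimulatorParams.from_yaml(path) == p
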