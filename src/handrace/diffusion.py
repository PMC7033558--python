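"""Single hand-posture simulator: a censored two-boundary drift-diffusion process.

One simulator accumulates evidence for "this posture can be made with my
hand" (upper boundary, *accept*) against "it cannot" (lower boundary,
*reject*).  A stochastic quit-timer is drawn per trial; if it elapses
before either boundary is reached the simulator gives up and returns a
forced *reject* ("I give up, it's not this hand").

The accumulator starts at ``threshold/2 + start_bias`` between absorbing
boundaries at 0 (reject) and ``threshold`` (accept) and evolves by
Euler–Maruyama integration.  Within-step boundary crossings are detected
with a Brownian-bridge correction (see :class:`SimulatorParams`), which
removes the O(sqrt(dt)) absorption bias of naive endpoint checking.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "SimulatorParams",
    "PassageResult",
    "ACCEPT",
    "REJECT",
    "QUIT",
    "EVENT_NAMES",
    "quit_lognormal_params",
    "draw_quit_time",
    "draw_quit_times",
    "simulate_passage",
    "simulate_passages",
    "absorption_oracle",
]

#: integer codes used by the vectorised simulator
ACCEPT, REJECT, QUIT = 1, 2, 3
EVENT_NAMES = {ACCEPT: "accept", REJECT: "reject", QUIT: "quit"}


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class SimulatorParams:
    """All parameters of one hand-posture diffusion simulator.

    Parameters
    ----------
    drift_rate:
        Mean evidence accumulation rate, evidence units per second.  The
        sign is applied per trial (positive when the stimulus matches the
        simulator's hand).
    threshold:
        Total boundary separation ``a`` (evidence units); boundaries sit
        at 0 (reject) and ``a`` (accept).
    start_bias:
        Signed offset ``z`` of the start point from the midpoint ``a/2``
        (evidence units).  Must satisfy ``|z| < a/2``.
    nondecision_time:
        Sensory/motor latency added once per trial (seconds).
    quit_mean, quit_sigma:
        Arithmetic mean and standard deviation (seconds) of the log-normal
        quit-timer under the default ``"arithmetic"`` parameterisation.
        Under ``quit_parameterization="log"`` they are instead the mean and
        SD of log-seconds (the underlying normal's parameters).
    noise_coef:
        Diffusion coefficient ``s``, evidence units per sqrt(second).
        Defaults to the classic 0.1 scaling convention.
    dt:
        Euler integration step (seconds).
    threshold_convention:
        How ``threshold`` maps onto boundary geometry.  ``"half"``
        (default): ``threshold`` is the distance from the unbiased start
        point to each boundary, i.e. total separation ``2 * threshold``
        (the symmetric +/-a convention of classic DDM simulation code).
        ``"full"``: ``threshold`` is the total boundary separation.
        Either way the accumulator runs between 0 (reject) and the total
        separation (accept), starting at the midpoint plus ``start_bias``.
    bridge_correction:
        If True (default), within-step boundary crossings are detected via
        the Brownian-bridge crossing probability, making absorption
        statistics nearly dt-unbiased.  Set False for plain endpoint
        detection.
    """

    drift_rate: float = 0.1
    threshold: float = 0.17
    start_bias: float = 0.0
    nondecision_time: float = 0.3
    quit_mean: float = 1.6
    quit_sigma: float = 1.0
    noise_coef: float = 0.1
    dt: float = 0.001
    quit_parameterization: str = "arithmetic"
    threshold_convention: str = "half"
    bridge_correction: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if self.threshold_convention not in ("half", "full"):
            raise ConfigError("threshold_convention must be 'half' or 'full'")
        if abs(self.start_bias) >= self.separation / 2:
            raise ConfigError("|start_bias| must be < half the boundary separation")
        if self.nondecision_time < 0:
            raise ConfigError("nondecision_time must be >= 0")
        if self.quit_mean <= 0 or self.quit_sigma <= 0:
            raise ConfigError("quit_mean and quit_sigma must be positive")
        if self.noise_coef <= 0:
            raise ConfigError("noise_coef must be positive")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.dt >= self.quit_mean:
            raise ConfigError("dt must be much smaller than quit_mean (timer unresolvable)")
        if self.quit_parameterization not in ("arithmetic", "log"):
            raise ConfigError("quit_parameterization must be 'arithmetic' or 'log'")

    @property
    def separation(self) -> float:
        """Total boundary separation implied by the threshold convention."""
        return 2.0 * self.threshold if self.threshold_convention == "half" else self.threshold

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulatorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "SimulatorParams":
        return replace(self, **changes)


class PassageResult(NamedTuple):
    """Outcome of one simulated first-passage trial.

    ``decision_time`` excludes the non-decision time.  For a quit event it
    equals the drawn quit-time.
    """

    event: str
    decision_time: float


def quit_lognormal_params(params: SimulatorParams) -> tuple[float, float]:
    """Underlying normal (mu, sigma) of the quit-timer's log-normal law.

    Under the arithmetic parameterisation the log-normal is moment-matched
    so that its arithmetic mean is ``quit_mean`` and arithmetic SD is
    ``quit_sigma``:  sigma^2 = ln(1 + (s/m)^2),  mu = ln(m) - sigma^2/2.
    """
    m, s = params.quit_mean, params.quit_sigma
    if params.quit_parameterization == "log":
        return float(np.log(m)), float(s)
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def draw_quit_times(params: SimulatorParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` strictly positive quit-times (seconds)."""
    mu, sigma = quit_lognormal_params(params)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def draw_quit_time(params: SimulatorParams, rng: np.random.Generator) -> float:
    """Draw a single quit-time (seconds) from the quit-timer distribution."""
    return float(draw_quit_times(params, 1, rng)[0])


def simulate_passages(
    params: SimulatorParams,
    drift_sign: int,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised first-passage simulation of ``n`` independent trials.

    Parameters
    ----------
    drift_sign:
        +1 when the stimulus is congruent with this simulator's hand
        (drift toward accept), -1 otherwise.

    Returns
    -------
    events:
        int8 array with codes ``ACCEPT``/``REJECT``/``QUIT``.
    decision_times:
        Seconds from accumulation onset to the terminating event
        (non-decision time not included).  Quit events carry their drawn
        quit-time exactly.

    Notes
    -----
    A quit and a boundary crossing detected in the same integration step
    resolve in favour of the crossing.
    """
    if drift_sign not in (+1, -1):
        raise ValueError("drift_sign must be +1 or -1")
    a = params.separation
    dt = params.dt
    mu_step = drift_sign * params.drift_rate * dt
    sig_step = params.noise_coef * np.sqrt(dt)
    s2dt = params.noise_coef**2 * dt

    quit_times = draw_quit_times(params, n, rng)
    events = np.zeros(n, dtype=np.int8)
    dec_times = np.empty(n, dtype=float)

    x = np.full(n, a / 2.0 + params.start_bias)
    idx = np.arange(n)  # indices of still-active trials
    step = 0
    while idx.size:
        step += 1
        t_now = step * dt
        x_old = x[idx]
        x_new = x_old + mu_step + sig_step * rng.standard_normal(idx.size)

        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        if params.bridge_correction:
            # Brownian bridge: prob the path touched a boundary within the
            # step even though both endpoints are inside.
            inside = ~(hit_up | hit_lo)
            if np.any(inside):
                xo, xn = x_old[inside], x_new[inside]
                p_up = np.exp(-2.0 * (a - xo) * (a - xn) / s2dt)
                p_lo = np.exp(-2.0 * xo * xn / s2dt)
                u = rng.random(xo.size)
                b_up = u < p_up
                b_lo = (~b_up) & (u < p_up + p_lo)
                hit_up[inside] |= b_up
                hit_lo[inside] |= b_lo
        # crossing wins over a quit resolving in the same step
        quit_now = (quit_times[idx] <= t_now) & ~hit_up & ~hit_lo

        done = hit_up | hit_lo | quit_now
        if np.any(done):
            gi = idx[done]
            ev = np.where(hit_up[done], ACCEPT, np.where(hit_lo[done], REJECT, QUIT))
            events[gi] = ev
            dec_times[gi] = np.where(ev == QUIT, quit_times[gi], t_now)
            keep = ~done
            x[idx] = x_new  # store positions before shrinking
            idx = idx[keep]
        else:
            x[idx] = x_new
    return events, dec_times


def simulate_passage(
    params: SimulatorParams, drift_sign: int, rng: np.random.Generator
) -> PassageResult:
    """Simulate a single trial; see :func:`simulate_passages`."""
    ev, t = simulate_passages(params, drift_sign, 1, rng)
    return PassageResult(EVENT_NAMES[int(ev[0])], float(t[0]))


def absorption_oracle(params: SimulatorParams, drift_sign: int) -> tuple[float, float]:
    """Closed-form Wiener absorption probability and mean first-passage time.

    For the *uncensored* process (no quit-timer) with total separation
    ``a`` (per the threshold convention), start ``w = a/2 + z``, drift
    ``v`` and diffusion ``s``:

        P(upper) = (1 - exp(-2 v w / s^2)) / (1 - exp(-2 v a / s^2))
        E[T]     = (a * P(upper) - w) / v

    with the drift -> 0 limits ``P = w/a`` and ``E[T] = w (a - w) / s^2``.
    Used as an independent validation oracle for the simulator.
    """
    a = params.separation
    w = a / 2.0 + params.start_bias
    v = drift_sign * params.drift_rate
    s2 = params.noise_coef**2
    if abs(v) < 1e-12 * params.noise_coef:
        p_up = w / a
        mean_t = w * (a - w) / s2
        return float(p_up), float(mean_t)
    k = 2.0 * v / s2
    p_up = -np.expm1(-k * w) / -np.expm1(-k * a)
    mean_t = (a * p_up - w) / v
    return float(p_up), float(mean_t)
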