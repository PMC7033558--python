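"""Race architectures composing hand-posture simulators, and grid fitting.

Two-handed controls carry one simulator per hand, run in parallel: the
first simulator to reach a terminal event (boundary crossing or quit)
determines the response.  An *accept* names that simulator's own hand; a
*reject* or *quit* names the other hand.  Congenital one-handers carry a
single intact-hand simulator, so a reject/quit maps to "missing".

The dominant/intact simulator carries the start-point bias ``+z`` and the
nondominant/missing simulator ``-z``.  Published group parameters: drift
0.1, bias z = 0.006, non-decision time 0.3 s, quit-timer mean 1.6 s and
sigma 1 s, with boundary separation 0.17 for controls and 0.138 for
congenital one-handers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .diffusion import (
    ACCEPT,
    EVENT_NAMES,
    SimulatorParams,
    simulate_passage,
    simulate_passages,
)

__all__ = [
    "HANDS",
    "Architecture",
    "TrialOutcome",
    "GroupPrediction",
    "control_architecture",
    "congenital_architecture",
    "run_trial",
    "simulate_group",
    "FitResult",
    "fit_parameters",
    "fit_groups",
]

HANDS = ("intact", "missing")


@dataclass(frozen=True)
class Architecture:
    """A group-level model: one or two hand-posture simulators.

    ``simulators`` maps hand labels to parameters.  Controls have both an
    ``"intact"`` (dominant) and a ``"missing"`` (nondominant) simulator;
    congenital one-handers only the ``"intact"`` one.
    """

    group_label: str
    simulators: Mapping[str, SimulatorParams]

    def __post_init__(self) -> None:
        keys = set(self.simulators)
        if self.group_label == "controls":
            if keys != {"intact", "missing"}:
                raise ValueError("controls need exactly the 'intact' and 'missing' simulators")
        elif self.group_label == "congenital":
            if keys != {"intact"}:
                raise ValueError("congenital needs exactly the 'intact' simulator")
        else:
            raise ValueError(f"unknown group_label {self.group_label!r}")
        ters = {p.nondecision_time for p in self.simulators.values()}
        if len(ters) != 1:
            raise ValueError("simulators must share nondecision_time")

    @property
    def nondecision_time(self) -> float:
        return next(iter(self.simulators.values())).nondecision_time

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "simulators": {h: p.to_dict() for h, p in self.simulators.items()},
        }


def control_architecture(
    drift_rate: float = 0.1,
    threshold: float = 0.17,
    bias: float = 0.006,
    **kwargs,
) -> Architecture:
    """Two-simulator architecture; +bias on the dominant/intact simulator."""
    return Architecture(
        "controls",
        {
            "intact": SimulatorParams(
                drift_rate=drift_rate, threshold=threshold, start_bias=+bias, **kwargs
            ),
            "missing": SimulatorParams(
                drift_rate=drift_rate, threshold=threshold, start_bias=-bias, **kwargs
            ),
        },
    )


def congenital_architecture(
    drift_rate: float = 0.1,
    threshold: float = 0.138,
    bias: float = 0.006,
    **kwargs,
) -> Architecture:
    """Single intact-hand simulator with +bias toward accepting the intact hand."""
    return Architecture(
        "congenital",
        {
            "intact": SimulatorParams(
                drift_rate=drift_rate, threshold=threshold, start_bias=+bias, **kwargs
            )
        },
    )


class TrialOutcome(NamedTuple):
    stimulus_hand: str
    response_hand: str
    rt: float  # deciding event's decision time + nondecision time, seconds
    correct: bool
    terminating_event: str


@dataclass(frozen=True)
class GroupPrediction:
    """Per-hand mean accuracy and mean correct RT, the fitted quantities."""

    group_label: str
    accuracy: Mapping[str, float]  # stimulus hand -> proportion correct
    mean_correct_rt: Mapping[str, float]  # stimulus hand -> seconds
    n_per_hand: int
    response_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h, acc in self.accuracy.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy[{h}] outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "accuracy": dict(self.accuracy),
            "mean_correct_rt": dict(self.mean_correct_rt),
            "n_per_hand": self.n_per_hand,
            "response_counts": dict(self.response_counts),
        }


def _other(hand: str) -> str:
    return "missing" if hand == "intact" else "intact"


def _race_batch(
    arch: Architecture, stimulus_hand: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised batch of trials for one stimulus hand.

    Returns (response_is_intact: bool, rt: seconds, deciding_event codes).
    """
    ter = arch.nondecision_time
    if arch.group_label == "congenital":
        sign = +1 if stimulus_hand == "intact" else -1
        ev, t = simulate_passages(arch.simulators["intact"], sign, n, rng)
        resp_intact = ev == ACCEPT
        return resp_intact, t + ter, ev

    ev_i, t_i = simulate_passages(
        arch.simulators["intact"], +1 if stimulus_hand == "intact" else -1, n, rng
    )
    ev_m, t_m = simulate_passages(
        arch.simulators["missing"], +1 if stimulus_hand == "missing" else -1, n, rng
    )
    intact_first = t_i < t_m
    tie = t_i == t_m
    if np.any(tie):
        intact_first = intact_first | (tie & (rng.random(n) < 0.5))
    dec_ev = np.where(intact_first, ev_i, ev_m)
    dec_t = np.where(intact_first, t_i, t_m)
    # accept -> deciding simulator's own hand; reject/quit -> the other hand
    resp_intact = np.where(dec_ev == ACCEPT, intact_first, ~intact_first)
    return resp_intact, dec_t + ter, dec_ev


def run_trial(arch: Architecture, stimulus_hand: str, rng: np.random.Generator) -> TrialOutcome:
    """Run one trial of the race; the earliest terminal event decides."""
    if stimulus_hand not in HANDS:
        raise ValueError(f"stimulus_hand must be one of {HANDS}")
    resp_intact, rt, ev = _race_batch(arch, stimulus_hand, 1, rng)
    response = "intact" if resp_intact[0] else "missing"
    return TrialOutcome(
        stimulus_hand=stimulus_hand,
        response_hand=response,
        rt=float(rt[0]),
        correct=response == stimulus_hand,
        terminating_event=EVENT_NAMES[int(ev[0])],
    )


def simulate_group(
    arch: Architecture, n_per_hand: int = 50_000, rng: np.random.Generator | None = None
) -> GroupPrediction:
    """Simulate ``n_per_hand`` trials per stimulus hand and summarise.

    Accuracy is the proportion of correct responses; mean RT is computed
    over correct trials only.
    """
    if n_per_hand < 1:
        raise ValueError("n_per_hand must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    accuracy: dict[str, float] = {}
    mean_rt: dict[str, float] = {}
    resp_counts = {"intact": 0, "missing": 0}
    for hand in HANDS:
        resp_intact, rt, _ = _race_batch(arch, hand, n_per_hand, rng)
        correct = resp_intact == (hand == "intact")
        accuracy[hand] = float(np.mean(correct))
        mean_rt[hand] = float(np.mean(rt[correct])) if np.any(correct) else float("nan")
        n_int = int(np.count_nonzero(resp_intact))
        resp_counts["intact"] += n_int
        resp_counts["missing"] += n_per_hand - n_int
    return GroupPrediction(
        group_label=arch.group_label,
        accuracy=accuracy,
        mean_correct_rt=mean_rt,
        n_per_hand=n_per_hand,
        response_counts=resp_counts,
    )


# ---------------------------------------------------------------------------
# Grid fitting to group-level means


class FitResult(NamedTuple):
    best_params: dict
    best_loss: float
    trace: list  # [(params dict, loss), ...] over the whole grid


def _prediction_loss(
    pred: GroupPrediction,
    target: GroupPrediction,
    weights: tuple[float, float],
) -> float:
    w_acc, w_rt = weights
    loss = 0.0
    for hand in HANDS:
        loss += w_acc * (pred.accuracy[hand] - target.accuracy[hand]) ** 2
        loss += w_rt * (pred.mean_correct_rt[hand] - target.mean_correct_rt[hand]) ** 2
    return loss


def fit_parameters(
    target: GroupPrediction,
    grid: Mapping[str, Sequence[float]],
    base: Mapping[str, float] | None = None,
    n_per_hand: int = 5_000,
    seed: int = 0,
    weights: tuple[float, float] = (1.0, 1.0),
) -> FitResult:
    """Exhaustive grid search minimising weighted squared error to targets.

    The automated stand-in for hand-tuning parameters to group-level RT
    and accuracy means.  ``grid`` maps architecture keyword names (e.g.
    ``threshold``, ``drift_rate``, ``bias``) to candidate values; ``base``
    holds fixed keywords.  Every grid point is evaluated with the same
    ``n_per_hand`` and the same seed (common random numbers), so the loss
    surface is deterministic and re-runnable.

    The loss is the equal-weight (unless ``weights`` overrides) sum over
    hands of squared accuracy error (proportion scale) plus squared mean
    correct-RT error (seconds scale).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    for h, acc in target.accuracy.items():
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"degenerate target accuracy for hand {h}")
    base = dict(base or {})
    builder = control_architecture if target.group_label == "controls" else congenital_architecture

    names = list(grid)
    trace: list[tuple[dict, float]] = []
    best: tuple[dict, float] | None = None
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        arch = builder(**{**base, **point})
        pred = simulate_group(arch, n_per_hand, np.random.default_rng(seed))
        loss = _prediction_loss(pred, target, weights)
        trace.append((point, loss))
        if best is None or loss < best[1]:
            best = (point, loss)
    assert best is not None
    return FitResult(best_params=best[0], best_loss=best[1], trace=trace)


def fit_groups(
    targets: Mapping[str, GroupPrediction],
    grid: Mapping[str, Sequence[float]],
    base: Mapping[str, float] | None = None,
    **kwargs,
) -> dict[str, FitResult]:
    """Fit each group independently over the same grid."""
    return {label: fit_parameters(t, grid, base, **kwargs) for label, t in targets.items()}
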