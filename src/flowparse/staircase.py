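"""Kesten (accelerated stochastic approximation) staircases.

Each track places the probe's scene-relative velocity on the next trial from
the running level

    level[n+1] = level[n] - c / (2 + m[n]) * (z[n] - phi)

where z is the binary response (1 = rightward), phi the target probability
of a rightward response, and m the number of response-category shifts so
far.  The step therefore shrinks as responses begin to alternate, and the
level converges to the phi-quantile of the observer's psychometric
function.  The constant c is calibrated so that the very first step — for
the response expected at the start level — equals the configured initial
step size.

Two tracks (descending toward the 20% point from +1 cm/s, ascending toward
the 80% point from -1 cm/s) are interleaved at random within a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "step_constant",
    "new_staircase",
    "kesten_update",
    "run_staircase",
    "run_interleaved_pair",
    "default_staircase_pair",
    "cumulative_gaussian_observer",
    "convergence_probabilities",
]


@dataclass(frozen=True)
class StaircaseConfig:
    start_level: float = 1.0     # cm/s
    initial_step: float = 0.33   # cm/s
    target_phi: float = 0.20     # probability of a rightward response
    n_trials: int = 50
    clip_range: float = 2.0      # |level| bound, cm/s

    def __post_init__(self) -> None:
        if not 0.0 < self.target_phi < 1.0:
            raise ValueError("target_phi must lie strictly in (0, 1)")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def step_constant(config: StaircaseConfig) -> float:
    """Calibrate c from the configured initial step.

    The response expected at the start level is rightward (z = 1) for a
    positive start and leftward (z = 0) for a negative one; the first step
    c/2 * |z - phi| is set equal to ``initial_step``.
    """
    z0 = 1.0 if config.start_level >= 0 else 0.0
    return 2.0 * config.initial_step / abs(z0 - config.target_phi)


@dataclass
class StaircaseState:
    """Evolving record of one adaptive track."""

    config: StaircaseConfig
    level: float
    c: float
    trial_index: int = 0
    m_shifts: int = 0
    prev_response: int | None = None
    history: list = field(default_factory=list)  # (level, response) pairs

    @property
    def done(self) -> bool:
        return self.trial_index >= self.config.n_trials


def new_staircase(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(config=config, level=config.start_level,
                          c=step_constant(config))


def kesten_update(state: StaircaseState, response: int) -> StaircaseState:
    """Record one response at the current level and step the level.

    ``response`` is z in {1 (right), 0 (left)}.  A response-category shift
    (z differing from the previous trial's z) increments m before the step
    is taken; the first trial never does.  Mutates and returns ``state``.
    """
    if state.done:
        raise RuntimeError("staircase already has its full trial count")
    z = int(response)
    if z not in (0, 1):
        raise ValueError("response must be 0 (left) or 1 (right)")
    if state.prev_response is not None and z != state.prev_response:
        state.m_shifts += 1
    state.history.append((state.level, z))
    phi = state.config.target_phi
    new_level = state.level - state.c / (2.0 + state.m_shifts) * (z - phi)
    clip = state.config.clip_range
    state.level = float(np.clip(new_level, -clip, clip))
    state.prev_response = z
    state.trial_index += 1
    return state


def run_staircase(observer, config: StaircaseConfig, rng) -> StaircaseState:
    """Run a single track to completion against an observer.

    ``observer(velocity, rng) -> z`` supplies the binary response at each
    presented level.
    """
    rng = np.random.default_rng(rng)
    state = new_staircase(config)
    while not state.done:
        kesten_update(state, observer(state.level, rng))
    return state


def cumulative_gaussian_observer(mu: float, sigma: float):
    """Observer callable whose P(right | v) = Phi((v - mu) / sigma)."""
    from scipy.stats import norm

    def respond(v, rng):
        return int(rng.random() < norm.cdf((v - mu) / sigma))

    return respond


def convergence_probabilities(config: StaircaseConfig, mu: float,
                              sigma: float, n_replicates: int,
                              rng, c_scale: float = 1.0) -> np.ndarray:
    """Generating-function response probability at the final level of
    repeated runs of one track against a cumulative-Gaussian observer.

    The mean of the returned array estimates where on the psychometric
    function the track actually converges; for a well-calibrated Kesten
    rule it should sit at ``config.target_phi``.  ``c_scale`` rescales the
    step constant (useful as a negative control: a miscalibrated constant
    shifts or slows convergence).
    """
    from scipy.stats import norm

    rng = np.random.default_rng(rng)
    observer = cumulative_gaussian_observer(mu, sigma)
    finals = np.empty(n_replicates)
    for i in range(n_replicates):
        state = new_staircase(config)
        state.c *= c_scale
        while not state.done:
            kesten_update(state, observer(state.level, rng))
        finals[i] = state.level
    return norm.cdf((finals - mu) / sigma)


def default_staircase_pair(n_trials: int = 50) -> tuple[StaircaseConfig, StaircaseConfig]:
    """The two tracks of the published design: descending from +1 cm/s to
    the 20% point, ascending from -1 cm/s to the 80% point."""
    return (StaircaseConfig(start_level=1.0, target_phi=0.20, n_trials=n_trials),
            StaircaseConfig(start_level=-1.0, target_phi=0.80, n_trials=n_trials))


def run_interleaved_pair(observer, staircase_configs, condition: str, rng,
                         probe_side: str = "right", session: int = 1,
                         interleave: str = "random") -> pd.DataFrame:
    """Run two interleaved staircases and return the trial table.

    On each trial one of the still-active tracks is chosen (uniformly at
    random, or strictly alternating with ``interleave="alternate"``); its
    level sets the probe's scene-relative velocity, and the observer's
    response updates only that track.  ``probe_side="random"`` draws the
    side independently on every trial, as in the published design.

    ``observer(velocity, rng) -> z`` as in :func:`run_staircase`; the caller
    closes over condition/probe-side specifics.  Columns: session,
    condition, probe_side, staircase_id, trial_index, velocity_cm_s,
    response_right.
    """
    if interleave not in ("random", "alternate"):
        raise ValueError("interleave must be 'random' or 'alternate'")
    if probe_side not in ("left", "right", "random"):
        raise ValueError("probe_side must be 'left', 'right' or 'random'")
    rng = np.random.default_rng(rng)
    states = [new_staircase(c) for c in staircase_configs]
    rows = []
    overall = 0
    while any(not s.done for s in states):
        active = [i for i, s in enumerate(states) if not s.done]
        if interleave == "random":
            i = active[rng.integers(len(active))] if len(active) > 1 else active[0]
        else:
            i = active[overall % len(active) if len(active) > 1 else 0]
        state = states[i]
        level = state.level
        if probe_side == "random":
            side = "left" if rng.random() < 0.5 else "right"
        else:
            side = probe_side
        z = int(observer(level, rng))
        kesten_update(state, z)
        rows.append((session, condition, side, i, state.trial_index - 1,
                     level, z))
        overall += 1
    return pd.DataFrame(rows, columns=[
        "session", "condition", "probe_side", "staircase_id", "trial_index",
        "velocity_cm_s", "response_right"])
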