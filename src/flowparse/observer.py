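"""Generative flow-parsing observer.

The observer receives the retinal velocity of the probe and an internal
estimate of the optic flow at the probe's location, and recovers
scene-relative motion by partial subtraction:

    perceived = retinal - g_global * F_global - g_local * F_local

``g_global`` is the gain on the globally estimated self-movement flow (the
component available even when no dots occupy the probe's hemifield);
``g_local`` is the gain on the local surround signal (centre-surround motion
contrast), present only when flow occupies the probe's hemifield.  Gains of
1 mean complete subtraction; gains below 1 leave an unparsed residual that
tilts (Experiment 2) or biases (Experiment 1) the percept.

Angles follow the paddle-report convention: degrees from rightward
horizontal, 90° = vertically upward, increasing counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "ObserverParams",
    "PerceivedMotion",
    "vector_angle_deg",
    "parse_flow",
    "flow_inputs_for_condition",
    "decide_exp1",
    "report_angle_exp2",
    "analytic_relative_tilt",
]


@dataclass(frozen=True)
class ObserverParams:
    """Per-participant generative parameters.

    Parameters
    ----------
    g_global, g_local : float
        Subtraction gains in [0, 1.5] for the global flow estimate and the
        local surround signal.
    sigma_disc : float
        Experiment 1 decision noise: SD (cm/s, scene units) of additive
        noise on the perceived scene-relative horizontal component.
    sigma_flow : float
        Optional multiplicative noise on each subtracted flow vector
        (SD as a fraction of its magnitude).
    sigma_report : float
        Experiment 2 angular report noise SD in degrees.
    lapse : float
        Probability of a uniformly random Experiment 1 response.
    age : float
        Years; annotation only, never used by the model.
    """

    g_global: float = 1.0
    g_local: float = 0.0
    sigma_disc: float = 0.0
    sigma_flow: float = 0.0
    sigma_report: float = 0.0
    lapse: float = 0.0
    age: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.g_global <= 1.5 and 0.0 <= self.g_local <= 1.5):
            raise ValueError("gains must lie in [0, 1.5]")
        if min(self.sigma_disc, self.sigma_flow, self.sigma_report) < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def with_(self, **kw) -> "ObserverParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


class PerceivedMotion(NamedTuple):
    vector: np.ndarray  # screen cm/s
    angle: float        # deg, 0 = rightward, 90 = up


def vector_angle_deg(v) -> float:
    """Direction of a 2-vector in degrees (0 = rightward, 90 = up,
    counterclockwise positive; range (-180, 180])."""
    v = np.asarray(v, dtype=float)
    if np.allclose(v, 0.0):
        raise ValueError("direction of the zero vector is undefined")
    return float(np.degrees(np.arctan2(v[1], v[0])))


def parse_flow(retinal_probe_velocity, global_flow_at_probe,
               local_flow_at_probe, params: ObserverParams,
               rng=None) -> PerceivedMotion:
    """Partial subtraction of the estimated flow from retinal probe motion.

    With ``sigma_flow`` > 0 each subtracted vector is scaled by an
    independent (1 + eps) factor, eps ~ Normal(0, sigma_flow); noiseless
    with g_local = 0 this is exact vector subtraction of the gain-scaled
    global flow.
    """
    retinal = np.asarray(retinal_probe_velocity, dtype=float)
    f_glob = np.asarray(global_flow_at_probe, dtype=float)
    f_loc = np.asarray(local_flow_at_probe, dtype=float)
    if not (np.all(np.isfinite(retinal)) and np.all(np.isfinite(f_glob))
            and np.all(np.isfinite(f_loc))):
        raise ValueError("velocity inputs must be finite")
    eps_g = eps_l = 0.0
    if params.sigma_flow > 0:
        rng = np.random.default_rng(rng)
        eps_g = rng.normal(0.0, params.sigma_flow)
        eps_l = rng.normal(0.0, params.sigma_flow)
    vec = (retinal
           - params.g_global * (1.0 + eps_g) * f_glob
           - params.g_local * (1.0 + eps_l) * f_loc)
    angle = vector_angle_deg(vec) if not np.allclose(vec, 0.0) else float("nan")
    return PerceivedMotion(vec, angle)


def flow_inputs_for_condition(configuration: str, flow_at_probe):
    """Flow signals available to the observer per hemifield configuration.

    The global self-movement estimate is available in every configuration
    (it is recovered from the whole field); the local surround signal exists
    only when dots occupy the probe's hemifield, so in the Opposite
    configuration the local input is zero.
    """
    flow = np.asarray(flow_at_probe, dtype=float)
    if configuration == "Opposite":
        return flow, np.zeros_like(flow)
    if configuration in ("Full", "Same"):
        return flow, flow.copy()
    raise ValueError(f"unknown configuration {configuration!r}")


def decide_exp1(perceived_scene_horizontal: float, params: ObserverParams,
                rng) -> str:
    """Binary left/right decision on the perceived scene-relative
    horizontal component.

    Responds "right" iff the component plus Normal(0, sigma_disc) noise is
    positive; with probability ``lapse`` the response is uniformly random.
    The induced response curve is a cumulative Gaussian in the scene-relative
    probe velocity with SD sigma_disc (compressed by the lapse rate).
    """
    rng = np.random.default_rng(rng)
    if params.lapse > 0 and rng.random() < params.lapse:
        return "right" if rng.random() < 0.5 else "left"
    x = perceived_scene_horizontal
    if params.sigma_disc > 0:
        x = x + rng.normal(0.0, params.sigma_disc)
    return "right" if x > 0 else "left"


def report_angle_exp2(perceived: PerceivedMotion, params: ObserverParams,
                      rng) -> float:
    """Paddle setting for the perceived trajectory: true perceived angle
    plus Normal(0, sigma_report) degrees, clipped to the paddle's
    [0, 180] range."""
    if np.allclose(perceived.vector, 0.0):
        raise ValueError("cannot report the direction of a zero percept")
    rng = np.random.default_rng(rng)
    angle = perceived.angle
    if params.sigma_report > 0:
        angle = angle + rng.normal(0.0, params.sigma_report)
    return float(np.clip(angle, 0.0, 180.0))


def analytic_relative_tilt(probe_velocity, flow_at_probe, g: float) -> float:
    """Closed-form relative tilt of the noiseless observer.

    Signed angle(probe - g*flow) - angle(probe) in degrees.  For a probe in
    the right hemifield the flow points outward (+x) and subtraction rotates
    the percept toward larger angles, i.e. toward the focus of expansion,
    giving a positive tilt; left-probe trials are sign-flipped downstream.
    """
    probe = np.asarray(probe_velocity, dtype=float)
    if np.allclose(probe, 0.0):
        raise ValueError("probe velocity must be nonzero")
    perceived = probe - g * np.asarray(flow_at_probe, dtype=float)
    if np.allclose(perceived, 0.0):
        raise ValueError("degenerate zero perceived vector")
    return vector_angle_deg(perceived) - vector_angle_deg(probe)
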