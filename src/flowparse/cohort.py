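"""Synthetic participant cohorts and end-to-end experiment simulation.

The cohort replaces the human sample: each synthetic participant is a
flow-parsing observer whose global subtraction gain increases linearly with
age (emulating the finding that the globally subtracted flow component
grows across adulthood) while the discrimination noises are age-constant
(emulating the finding that scene-relative motion sensitivity is
preserved).  Defaults give a gain span of roughly 0.4 at age 20 to 0.9 at
age 76 and a moving/static noise ratio of 1.5, so the recovered
flow-parsing index centres on 1.5 at every age.

All randomness flows from a single master seed; identical seeds reproduce
identical trial tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .geometry import (SceneConfig, FlowConfig, probe_kinematics_exp1,
                       flow_at_probe_exp1, flow_speed_at_probe_exp2)
from .observer import (ObserverParams, parse_flow, flow_inputs_for_condition,
                       decide_exp1, report_angle_exp2)
from .staircase import StaircaseConfig, default_staircase_pair, \
    run_interleaved_pair
from .tilt import recode_configuration

__all__ = [
    "CohortSpec",
    "SimulatedDataset",
    "generate_cohort",
    "exp1_response_slope",
    "simulate_experiment1",
    "simulate_experiment2",
    "simulate_dataset",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    The age -> gain map is g_global = intercept + slope * age plus optional
    Normal between-subject jitter, clipped to the observer's gain bounds.
    Discrimination noises receive a shared multiplicative log-normal jitter
    so the moving/static ratio (the quantity the flow-parsing index
    estimates) stays fixed within a participant.
    """

    n_participants: int = 30
    age_range: tuple = (20.0, 76.0)
    g_global_intercept: float = 0.25
    g_global_age_slope: float = 1.0 / 120.0   # per year: 0.417 -> 0.883 over 20-76
    g_global_jitter_sd: float = 0.08
    g_local: float = 0.2
    sigma_disc_static: float = 0.15           # cm/s
    sigma_disc_moving: float = 0.225          # cm/s; ratio 1.5 vs static
    sigma_disc_jitter_sd: float = 0.15        # log-normal, shared across conditions
    sigma_report: float = 5.0                 # deg
    sigma_flow: float = 0.0
    lapse: float = 0.0
    missing_second_session: int = 0           # participants with one session only
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.missing_second_session < 0:
            raise ValueError("missing_second_session must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d


@dataclass
class SimulatedDataset:
    participants: pd.DataFrame
    exp1_trials: pd.DataFrame
    exp2_trials: pd.DataFrame
    spec: CohortSpec = field(repr=False, default=None)


def generate_cohort(spec: CohortSpec, rng=None,
                    ages=None) -> pd.DataFrame:
    """Draw the participant table: ids, ages, and true observer parameters.

    Ages are uniform over ``spec.age_range`` unless an explicit list is
    supplied.  Gains are deterministic functions of age plus the configured
    jitter.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_participants
    if ages is None:
        ages = rng.uniform(*spec.age_range, n)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != n:
        raise ValueError("ages list length must match n_participants")
    g_global = spec.g_global_intercept + spec.g_global_age_slope * ages
    if spec.g_global_jitter_sd > 0:
        g_global = g_global + rng.normal(0.0, spec.g_global_jitter_sd, n)
    g_global = np.clip(g_global, 0.0, 1.5)
    noise_mult = np.ones(n)
    if spec.sigma_disc_jitter_sd > 0:
        noise_mult = np.exp(rng.normal(0.0, spec.sigma_disc_jitter_sd, n))
    sessions = np.full(n, 2)
    if spec.missing_second_session:
        single = rng.choice(n, size=spec.missing_second_session, replace=False)
        sessions[single] = 1
    return pd.DataFrame({
        "participant_id": [f"P{i + 1:02d}" for i in range(n)],
        "age": ages,
        "g_global": g_global,
        "g_local": spec.g_local,
        "sigma_disc_static": spec.sigma_disc_static * noise_mult,
        "sigma_disc_moving": spec.sigma_disc_moving * noise_mult,
        "sigma_report": spec.sigma_report,
        "sigma_flow": spec.sigma_flow,
        "lapse": spec.lapse,
        "n_sessions": sessions,
    })


def exp1_response_slope(config: SceneConfig, t: float | None = None
                        ) -> tuple[float, float]:
    """Linear response model coefficients for Experiment 1.

    Both the retinal probe velocity and the flow at the probe are linear in
    the scene-relative velocity v (the probe starts at the focus of
    expansion, so both vanish at v = 0).  Returns (d, b): retinal and flow
    screen velocities per unit v, evaluated at the trial midpoint, so the
    perceived scene-relative component of the partial-subtraction observer
    is v * (d - g * b) * Z_mid / f.
    """
    if t is None:
        t = config.motion_duration / 2.0
    d = probe_kinematics_exp1(1.0, "moving", config, "right", t).velocity[0] \
        - probe_kinematics_exp1(0.0, "moving", config, "right", t).velocity[0]
    b = flow_at_probe_exp1(1.0, config, "right", t)[0] \
        - flow_at_probe_exp1(0.0, config, "right", t)[0]
    return float(d), float(b)


def _exp1_observer(params: ObserverParams, condition: str,
                   config: SceneConfig):
    """Observer callable (velocity, rng) -> z for the staircase driver."""
    f = config.viewing_distance
    if condition == "static":
        z0 = config.array_distance
        scale = f / z0  # projection of the lateral scene velocity

        def respond(v, rng):
            perceived_screen = scale * v  # no flow to parse
            perceived_scene = perceived_screen * z0 / f
            return 1 if decide_exp1(perceived_scene, params, rng) == "right" else 0

        return respond

    t_mid = config.motion_duration / 2.0
    d, b = exp1_response_slope(config, t_mid)
    z_mid = config.array_distance - np.cos(
        np.radians(config.probe_eccentricity)) * config.self_speed * t_mid

    def respond(v, rng):
        g = params.g_global
        if params.sigma_flow > 0:
            g = g * (1.0 + rng.normal(0.0, params.sigma_flow))
        perceived_screen = v * (d - g * b)
        perceived_scene = perceived_screen * z_mid / f
        return 1 if decide_exp1(perceived_scene, params, rng) == "right" else 0

    return respond


def _observer_params(row, condition: str | None = None) -> ObserverParams:
    sigma_disc = 0.0
    if condition is not None:
        sigma_disc = float(row[f"sigma_disc_{condition}"])
    return ObserverParams(
        g_global=float(row["g_global"]), g_local=float(row["g_local"]),
        sigma_disc=sigma_disc, sigma_flow=float(row["sigma_flow"]),
        sigma_report=float(row["sigma_report"]), lapse=float(row["lapse"]),
        age=float(row["age"]))


def simulate_experiment1(participants: pd.DataFrame,
                         scene_config: SceneConfig | None = None,
                         staircase_configs=None,
                         seed=None) -> pd.DataFrame:
    """Simulate the staircase experiment for every participant.

    Per participant x condition x session, two interleaved Kesten tracks of
    50 trials each are run against the participant's observer (static: no
    flow; moving: focus of expansion at the probe's initial position).
    Yields 200 trials per condition for two-session participants.
    """
    scene_config = scene_config or SceneConfig()
    if staircase_configs is None:
        staircase_configs = default_staircase_pair()
    rng = np.random.default_rng(seed)
    tables = []
    for row in participants.itertuples(index=False):
        row = row._asdict()
        n_sessions = int(row.get("n_sessions", 2))
        for condition in ("static", "moving"):
            params = _observer_params(row, condition)
            respond = _exp1_observer(params, condition, scene_config)
            for session in range(1, n_sessions + 1):
                tbl = run_interleaved_pair(
                    respond, staircase_configs, condition, rng,
                    probe_side="random", session=session)
                tbl.insert(0, "participant_id", row["participant_id"])
                tbl.insert(1, "age", row["age"])
                tables.append(tbl)
    return pd.concat(tables, ignore_index=True)


def _exp2_trial_list(rng, n_sessions: int,
                     config: FlowConfig) -> pd.DataFrame:
    frames = []
    for session in range(1, n_sessions + 1):
        rows = [(session, mask, side, angle)
                for _ in range(6)
                for angle in config.probe_angles
                for mask in ("Full", "HemiL", "HemiR")
                for side in ("left", "right")]
        order = rng.permutation(len(rows))
        frames.append(pd.DataFrame(
            [rows[i] for i in order],
            columns=["session", "field_mask", "probe_side", "probe_angle_deg"]))
    return pd.concat(frames, ignore_index=True)


def simulate_experiment2(participants: pd.DataFrame,
                         flow_config: FlowConfig | None = None,
                         seed=None) -> pd.DataFrame:
    """Simulate the paddle-report experiment for every participant.

    Each session presents the full factorial (3 probe angles x 3 flow
    fields x 2 probe sides x 6 repetitions = 108 trials) in randomized
    order.  The reported angle comes from the partial-subtraction observer:
    the flow at the probe is horizontal and outward, the local component is
    removed in the Opposite configuration, and the paddle setting adds the
    angular report noise.
    """
    flow_config = flow_config or FlowConfig()
    rng = np.random.default_rng(seed)
    flow_speed = flow_speed_at_probe_exp2(flow_config)
    tables = []
    for row in participants.itertuples(index=False):
        row = row._asdict()
        params = _observer_params(row)
        trials = _exp2_trial_list(rng, int(row.get("n_sessions", 2)),
                                  flow_config)
        reported = np.empty(len(trials))
        for i, tr in enumerate(trials.itertuples(index=False)):
            sign = 1.0 if tr.probe_side == "right" else -1.0
            flow_vec = np.array([sign * flow_speed, 0.0])
            theta = np.radians(tr.probe_angle_deg)
            probe_vec = flow_config.probe_speed * np.array(
                [np.cos(theta), np.sin(theta)])
            configuration = recode_configuration(tr.field_mask, tr.probe_side)
            f_glob, f_loc = flow_inputs_for_condition(configuration, flow_vec)
            perceived = parse_flow(probe_vec, f_glob, f_loc, params, rng)
            reported[i] = report_angle_exp2(perceived, params, rng)
        trials["reported_angle_deg"] = reported
        trials.insert(0, "participant_id", row["participant_id"])
        trials.insert(1, "age", row["age"])
        tables.append(trials)
    return pd.concat(tables, ignore_index=True)


def simulate_dataset(spec: CohortSpec,
                     scene_config: SceneConfig | None = None,
                     flow_config: FlowConfig | None = None,
                     staircase_configs=None,
                     seed=None) -> SimulatedDataset:
    """Generate a cohort and both experiments from one master seed."""
    master = np.random.default_rng(spec.seed if seed is None else seed)
    cohort_rng, exp1_rng, exp2_rng = master.spawn(3)
    participants = generate_cohort(spec, rng=cohort_rng)
    exp1 = simulate_experiment1(participants, scene_config,
                                staircase_configs, seed=exp1_rng)
    exp2 = simulate_experiment2(participants, flow_config, seed=exp2_rng)
    return SimulatedDataset(participants=participants, exp1_trials=exp1,
                            exp2_trials=exp2, spec=spec)
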