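"""Relative-tilt analysis: equivalent-90° transform, hemifield recoding,
and the local/global decomposition.

Relative tilt (RelT) is the signed angular difference between the reported
and physical probe trajectories, with positive meaning tilt toward the
focus of expansion (inward).  Tilts measured at the 75° and 105° probe
angles are transformed into the tilt an identical *horizontal* illusory
motion component would produce on a vertical (90°) probe, after which the
three probe angles can be pooled.

Per-hemifield flow fields are recoded as Full / Same / Opposite relative to
the probe's side.  In the Opposite configuration no dots neighbour the
probe, so any tilt there reflects global flow subtraction alone; the local
surround contribution is isolated as Same - Opposite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TiltSummary",
    "relative_tilt",
    "equivalent_90",
    "invert_equivalent_90",
    "recode_configuration",
    "collapsed_probe_angle",
    "summarize_participant",
    "summarize_cohort",
    "gain_from_global_tilt",
]

CONFIGURATIONS = ("Full", "Same", "Opposite")


@dataclass(frozen=True)
class TiltSummary:
    """Per-participant mean relative tilts (deg) by configuration."""

    relT_full: float
    relT_same: float
    relT_opposite: float
    relT_global: float   # = relT_opposite
    relT_local: float    # = relT_same - relT_opposite
    n_trials_per_config: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def relative_tilt(reported_angle: float, probe_angle: float,
                  probe_side: str) -> float:
    """Signed relative tilt in degrees, positive toward the focus of
    expansion.

    For a right-side probe inward is leftward, i.e. toward larger paddle
    angles, so the tilt is reported minus actual; left-probe trials have
    the sign flipped so inward is positive on both sides.
    """
    if not (0.0 <= reported_angle <= 180.0 and 0.0 <= probe_angle <= 180.0):
        raise ValueError("angles must lie in [0, 180] degrees")
    raw = reported_angle - probe_angle
    if probe_side == "right":
        return float(raw)
    if probe_side == "left":
        return float(-raw)
    raise ValueError(f"unknown probe_side {probe_side!r}")


def equivalent_90(relT: float, probe_angle: float,
                  probe_speed: float = 0.8) -> float:
    """Map a tilt at probe angle theta to the equivalent tilt at 90°.

    In the side-collapsed, inward-positive frame the probe moves at speed v
    along theta and the illusory motion is a horizontal component h (inward
    positive) satisfying

        tan(theta + relT) = v sin(theta) / (v cos(theta) - h),

    which gives h = v sin(relT) / sin(theta + relT).  A vertical probe
    carrying the same h would be tilted by atan(h / v); at theta = 90° the
    transform is the identity.  The probe speed cancels from the result but
    is kept in the signature because h itself is a velocity.
    """
    if not -probe_angle < relT < 180.0 - probe_angle:
        raise ValueError(
            f"relT={relT} leaves the perceived direction outside (0, 180) "
            f"for a {probe_angle} deg probe")
    del probe_speed  # h/v is independent of the speed
    th = np.radians(probe_angle)
    r = np.radians(relT)
    ratio = np.sin(r) / np.sin(th + r)
    return float(np.degrees(np.arctan(ratio)))


def invert_equivalent_90(eq_tilt: float, probe_angle: float,
                         probe_speed: float = 0.8) -> float:
    """Tilt at probe angle theta that maps to ``eq_tilt`` at 90°
    (numerical inverse of :func:`equivalent_90`)."""
    if not -90.0 < eq_tilt < 90.0:
        raise ValueError("equivalent tilt must lie in (-90, 90)")
    target = np.tan(np.radians(eq_tilt))
    lo, hi = -probe_angle + 1e-9, 180.0 - probe_angle - 1e-9

    def f(r):
        return (np.sin(np.radians(r))
                / np.sin(np.radians(probe_angle + r))) - target

    return float(brentq(f, lo, hi, xtol=1e-12))


def recode_configuration(field_mask: str, probe_side: str) -> str:
    """Full / Same / Opposite relative to the probe's hemifield."""
    if field_mask == "Full":
        if probe_side not in ("left", "right"):
            raise ValueError(f"unknown probe_side {probe_side!r}")
        return "Full"
    try:
        flow_side = {"HemiL": "left", "HemiR": "right"}[field_mask]
    except KeyError:
        raise ValueError(f"unknown field_mask {field_mask!r}") from None
    if probe_side not in ("left", "right"):
        raise ValueError(f"unknown probe_side {probe_side!r}")
    return "Same" if probe_side == flow_side else "Opposite"


def collapsed_probe_angle(probe_angle: float, probe_side: str) -> float:
    """Probe angle in the side-collapsed (as-if-right) frame.

    Mirroring a left-probe trial about the vertical axis maps a trajectory
    at global angle theta to 180° - theta, so a left probe moving at 75°
    plays the role of a right probe moving at 105°.
    """
    return probe_angle if probe_side == "right" else 180.0 - probe_angle


def summarize_participant(trials: pd.DataFrame,
                          probe_speed: float = 0.8) -> TiltSummary:
    """Full tilt pipeline for one participant's trial table.

    Expects columns field_mask, probe_side, probe_angle_deg,
    reported_angle_deg.  Per trial: signed relative tilt -> equivalent-90°
    transform (using the side-collapsed probe angle) -> Full/Same/Opposite
    recoding; then configuration means and the decomposition
    Global = Opposite, Local = Same - Opposite.  Trials whose perceived
    direction falls at or beyond horizontal (where the transform is
    undefined) are excluded and counted.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    per_config: dict[str, list[float]] = {c: [] for c in CONFIGURATIONS}
    excluded = 0
    for row in trials.itertuples(index=False):
        rel = relative_tilt(row.reported_angle_deg, row.probe_angle_deg,
                            row.probe_side)
        theta = collapsed_probe_angle(row.probe_angle_deg, row.probe_side)
        try:
            eq = equivalent_90(rel, theta, probe_speed)
        except ValueError:
            excluded += 1
            continue
        per_config[recode_configuration(row.field_mask, row.probe_side)].append(eq)
    for cfg, vals in per_config.items():
        if not vals:
            raise ValueError(f"no usable trials in configuration {cfg}")
    means = {c: float(np.mean(v)) for c, v in per_config.items()}
    return TiltSummary(
        relT_full=means["Full"],
        relT_same=means["Same"],
        relT_opposite=means["Opposite"],
        relT_global=means["Opposite"],
        relT_local=means["Same"] - means["Opposite"],
        n_trials_per_config=min(len(v) for v in per_config.values()),
        n_excluded=excluded,
    )


def summarize_cohort(trials: pd.DataFrame,
                     probe_speed: float = 0.8) -> pd.DataFrame:
    """Per-participant tilt summaries over a cohort trial table
    (requires a participant_id column)."""
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        summary = summarize_participant(grp, probe_speed)
        rec = {"participant_id": pid}
        if "age" in grp.columns:
            rec["age"] = float(grp["age"].iloc[0])
        rec.update(summary.to_dict())
        rows.append(rec)
    return pd.DataFrame(rows)


def gain_from_global_tilt(relT_global: float, probe_speed: float,
                          flow_speed: float) -> float:
    """Invert the noiseless tilt model for the global subtraction gain.

    After the equivalent-90° transform the probe is vertical (speed v) and
    the subtracted flow horizontal (speed F), so relT = atan(g F / v) and
    g = v tan(relT) / F.
    """
    if flow_speed <= 0:
        raise ValueError("flow speed must be positive")
    if not -90.0 < relT_global < 90.0:
        raise ValueError("global tilt must lie in (-90, 90)")
    return float(probe_speed * np.tan(np.radians(relT_global)) / flow_speed)
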