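"""Synthetic repeated-measures gait cohort generator.

Emulates the output of a motion-capture + musculoskeletal-simulation front
end for a 15-participant, four-condition (neutral, toe-in, toe-out,
lateral wedge insoles), five-trial repeated-measures walking study.  Each
scalar feature is drawn as

    condition_mean + participant_intercept + trial_noise

with the participant intercept carrying ``between_participant_sd_fraction``
of the feature SD (shared across conditions, which induces the
within-subject correlation a repeated-measures analysis relies on) and the
trial noise carrying the remainder in quadrature.  Features are mutually
independent given the intercepts; draws violating physical bounds
(non-positive forces, strides, velocities, or a mean stance force above
the peak) are resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CONDITION_MEANS",
    "CONDITION_SDS",
    "CohortConfig",
    "generate_cohort",
    "generate_cop_trajectory",
]

CONDITIONS = ("neutral", "toe_in", "toe_out", "lateral_insoles")

#: Feature names (and units) of one gait trial.
FEATURES = (
    "peak_force_bw",          # peak medial compressive force, BW
    "mean_stance_force_bw",   # stance-mean medial compressive force, BW
    "flexion_angle_deg",      # knee flexion at the instant of peak force
    "stride_length_m",
    "velocity_mps",
    "cop_offset_mm",          # + = CoP lateral of the foot centre of mass
    "foot_progression_deg",   # + = toe-out
)

# Per-condition generating means.  Peak force, stride, velocity, CoP offset
# and foot progression are published cohort values; the stance-mean force is
# back-derived from the published cumulative load (mean force / stride), and
# the flexion angle at peak force (unpublished) defaults to a typical
# early-stance 20 degrees in every condition.
CONDITION_MEANS: dict[str, dict[str, float]] = {
    "neutral": dict(
        peak_force_bw=2.68, mean_stance_force_bw=0.85 * 1.71,
        flexion_angle_deg=20.0, stride_length_m=1.71, velocity_mps=1.54,
        cop_offset_mm=1.39, foot_progression_deg=3.51,
    ),
    "toe_in": dict(
        peak_force_bw=2.51, mean_stance_force_bw=0.81 * 1.72,
        flexion_angle_deg=20.0, stride_length_m=1.72, velocity_mps=1.49,
        cop_offset_mm=8.45, foot_progression_deg=-10.63,
    ),
    "toe_out": dict(
        peak_force_bw=2.43, mean_stance_force_bw=0.80 * 1.74,
        flexion_angle_deg=20.0, stride_length_m=1.74, velocity_mps=1.49,
        cop_offset_mm=-4.58, foot_progression_deg=11.95,
    ),
    "lateral_insoles": dict(
        peak_force_bw=2.69, mean_stance_force_bw=0.84 * 1.71,
        flexion_angle_deg=20.0, stride_length_m=1.71, velocity_mps=1.56,
        cop_offset_mm=-1.03, foot_progression_deg=2.33,
    ),
}

# Matching SDs; stance-mean force SD = cumulative-load SD x stride mean.
CONDITION_SDS: dict[str, dict[str, float]] = {
    "neutral": dict(
        peak_force_bw=0.47, mean_stance_force_bw=0.09 * 1.71,
        flexion_angle_deg=5.0, stride_length_m=0.10, velocity_mps=0.11,
        cop_offset_mm=5.12, foot_progression_deg=5.86,
    ),
    "toe_in": dict(
        peak_force_bw=0.46, mean_stance_force_bw=0.13 * 1.72,
        flexion_angle_deg=5.0, stride_length_m=0.11, velocity_mps=0.15,
        cop_offset_mm=8.05, foot_progression_deg=3.91,
    ),
    "toe_out": dict(
        peak_force_bw=0.46, mean_stance_force_bw=0.09 * 1.74,
        flexion_angle_deg=5.0, stride_length_m=0.12, velocity_mps=0.11,
        cop_offset_mm=7.63, foot_progression_deg=2.25,
    ),
    "lateral_insoles": dict(
        peak_force_bw=0.49, mean_stance_force_bw=0.09 * 1.71,
        flexion_angle_deg=5.0, stride_length_m=0.09, velocity_mps=0.12,
        cop_offset_mm=4.25, foot_progression_deg=3.10,
    ),
}

#: Features whose draws must stay strictly positive.
_POSITIVE = {"peak_force_bw", "mean_stance_force_bw", "stride_length_m",
             "velocity_mps"}

COHORT_COLUMNS = ["participant_id", "condition", "body_mass_kg", *FEATURES]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_participants: int = 15
    n_trials: int = 5
    seed: int = 0
    between_participant_sd_fraction: float = 0.7
    body_mass_mean_kg: float = 69.31
    body_mass_sd_kg: float = 9.92
    condition_means: dict = field(
        default_factory=lambda: {c: dict(m) for c, m in CONDITION_MEANS.items()}
    )
    condition_sds: dict = field(
        default_factory=lambda: {c: dict(s) for c, s in CONDITION_SDS.items()}
    )

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if not (0.0 <= self.between_participant_sd_fraction <= 1.0):
            raise ValueError(
                "between_participant_sd_fraction must lie in [0, 1]"
            )
        if self.body_mass_sd_kg < 0:
            raise ValueError("body_mass_sd_kg must be non-negative")
        for cond in CONDITIONS:
            if cond not in self.condition_means or cond not in self.condition_sds:
                raise ValueError(f"missing condition block {cond!r}")
            for feat in FEATURES:
                if self.condition_sds[cond][feat] < 0:
                    raise ValueError(f"negative SD for {cond}/{feat}")


def _resample_where(
    rng: np.random.Generator,
    values: np.ndarray,
    centre: np.ndarray,
    sd: float,
    bad: np.ndarray,
) -> None:
    """Redraw flagged entries in place until none remain non-positive."""
    guard = 0
    while np.any(bad):
        values[bad] = rng.normal(centre[bad], sd)
        bad = values <= 0.0
        guard += 1
        if guard > 1000:  # pragma: no cover - pathological config
            raise RuntimeError("resampling failed to satisfy bounds")


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw the full trial-level gait-feature table.

    Returns a tidy DataFrame with one row per participant x condition x
    trial; identical seeds give identical tables.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    frac = config.between_participant_sd_fraction
    noise_frac = math.sqrt(max(0.0, 1.0 - frac * frac))

    n_p, n_t = config.n_participants, config.n_trials
    masses = rng.normal(config.body_mass_mean_kg, config.body_mass_sd_kg, n_p)
    _resample_where(
        rng, masses, np.full(n_p, config.body_mass_mean_kg),
        config.body_mass_sd_kg, masses <= 0.0,
    )
    # one standard-normal intercept per participant per feature, shared
    # across conditions so that features correlate within a participant
    intercepts = {feat: rng.normal(0.0, 1.0, n_p) for feat in FEATURES}

    blocks: list[pd.DataFrame] = []
    pids = np.array([f"P{i + 1:02d}" for i in range(n_p)])
    for cond in CONDITIONS:
        means = config.condition_means[cond]
        sds = config.condition_sds[cond]
        draws: dict[str, np.ndarray] = {}
        centres: dict[str, np.ndarray] = {}
        for feat in FEATURES:
            centre = (
                means[feat] + frac * sds[feat] * intercepts[feat]
            )[:, None] * np.ones((1, n_t))
            noise_sd = noise_frac * sds[feat]
            vals = rng.normal(centre, noise_sd)
            if feat in _POSITIVE:
                _resample_where(rng, vals, centre, noise_sd, vals <= 0.0)
            centres[feat] = centre
            draws[feat] = vals
        # enforce peak >= stance-mean force by resampling the pair
        bad = draws["peak_force_bw"] < draws["mean_stance_force_bw"]
        guard = 0
        while np.any(bad):
            for feat in ("peak_force_bw", "mean_stance_force_bw"):
                noise_sd = noise_frac * sds[feat]
                vals = draws[feat]
                vals[bad] = rng.normal(centres[feat][bad], noise_sd)
                _resample_where(rng, vals, centres[feat], noise_sd, vals <= 0.0)
            bad = draws["peak_force_bw"] < draws["mean_stance_force_bw"]
            guard += 1
            if guard > 1000:  # pragma: no cover
                raise RuntimeError("force-ordering resampling failed")
        block = {
            "participant_id": np.repeat(pids, n_t),
            "condition": cond,
            "body_mass_kg": np.repeat(masses, n_t),
        }
        block.update({feat: draws[feat].ravel() for feat in FEATURES})
        blocks.append(pd.DataFrame(block, columns=COHORT_COLUMNS))
    out = pd.concat(blocks, ignore_index=True)
    # row order: participant-major, then condition, then trial
    out = out.sort_values(
        ["participant_id", "condition"],
        key=lambda s: (
            s.map({c: i for i, c in enumerate(CONDITIONS)})
            if s.name == "condition"
            else s
        ),
        kind="stable",
    ).reset_index(drop=True)
    return out


def generate_cop_trajectory(
    progression_angle: float,
    stance_duration: float = 0.7,
    n_samples: int = 700,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ap_excursion: float = 180.0,
):
    """Straight-line centre-of-pressure path at a known progression angle.

    The path runs from initial contact to toe-off covering ``ap_excursion``
    mm anteriorly; its heading relative to the anterior axis equals
    ``progression_angle`` degrees (positive toe-out, i.e. toward lateral),
    with optional Gaussian mediolateral noise.  Returns a
    :class:`~medialknee.gait.Trajectory` with channels (ml, ap) in mm.
    """
    from .gait import Trajectory

    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if stance_duration <= 0:
        raise ValueError("stance_duration must be positive")
    times = np.linspace(0.0, stance_duration, n_samples)
    ap = np.linspace(0.0, ap_excursion, n_samples)
    ml = ap * math.tan(math.radians(progression_angle))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ml = ml + rng.normal(0.0, noise_sd, n_samples)
    return Trajectory(times=times, values=np.column_stack([ml, ap]),
                      channels=("ml", "ap"))
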