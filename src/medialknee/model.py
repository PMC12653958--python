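"""Cohort-level model: per-trial contact + failure computation, condition
summaries, and the repeated-measures comparison, packaged as a
statsmodels-style Model/Results pair.

`CartilageLifetimeModel` is built from a trial-level gait-feature table
(one row per participant x condition x trial, the schema produced by
:mod:`medialknee.cohort`).  `fit()` runs the elastic-foundation contact
solve for every trial, feeds the resulting peak strain and stressed volume
into the Weibull failure-with-repair model, aggregates trial -> participant
mean -> condition statistics (the repeated-measures order), fits the mixed
model per outcome, and returns a `CartilageLifetimeResults` carrying the
per-trial table, the per-condition summary, the pairwise contrasts, the
per-condition mean failure-probability time series and a `summary()`
table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CONDITIONS, CohortConfig, generate_cohort
from .contact import (
    GRAVITY,
    CartilageMaterial,
    ContactMesh,
    ContactSolverError,
    KneeGeometry,
    build_mesh,
    solve_contact,
)
from .failure import FailureParams, p_fail_with_repair, time_to_failure
from .gait import cumulative_load, daily_loading_cycles
from .stats import ConditionComparison, fit_condition_model

__all__ = [
    "CartilageLifetimeModel",
    "CartilageLifetimeResults",
    "DEFAULT_OUTCOMES",
]

#: Outcomes summarised and compared across conditions, in reporting order.
DEFAULT_OUTCOMES = (
    "peak_force_bw",
    "cumulative_load_bw_per_m",
    "daily_cycles",
    "peak_stress_mpa",
    "peak_strain",
    "p_fail_with_repair_pct",
    "p_fail_no_repair_pct",
)

_REQUIRED_COLUMNS = (
    "participant_id",
    "condition",
    "body_mass_kg",
    "peak_force_bw",
    "mean_stance_force_bw",
    "flexion_angle_deg",
    "stride_length_m",
)


class CartilageLifetimeModel:
    """Medial tibiofemoral loading and lifetime failure risk for a cohort.

    Parameters
    ----------
    data:
        Trial-level gait features; must contain the columns
        ``participant_id, condition, body_mass_kg, peak_force_bw,
        mean_stance_force_bw, flexion_angle_deg, stride_length_m``.
    geometry, material, failure_params:
        Model stages' configuration; defaults reproduce the reference
        parameterisation.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        geometry: KneeGeometry | None = None,
        material: CartilageMaterial | None = None,
        failure_params: FailureParams | None = None,
    ) -> None:
        self.data = self._validate(data)
        self.geometry = geometry or KneeGeometry()
        self.material = material or CartilageMaterial()
        self.failure_params = failure_params or FailureParams()
        self._mesh: ContactMesh | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CartilageLifetimeModel":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CartilageLifetimeModel":
        return cls(pd.read_csv(path), **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: CohortConfig | None = None, **kwargs
    ) -> "CartilageLifetimeModel":
        """Build directly from the synthetic cohort generator."""
        return cls(generate_cohort(config), **kwargs)

    # -- validation -------------------------------------------------------
    @staticmethod
    def _validate(data: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in _REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns {missing}")
        problems = []
        for i, row in data.iterrows():
            if row["condition"] not in CONDITIONS:
                problems.append(f"row {i}: unknown condition {row['condition']!r}")
            if not row["peak_force_bw"] > 0:
                problems.append(f"row {i}: peak_force_bw must be positive")
            if not row["stride_length_m"] > 0:
                problems.append(f"row {i}: stride_length_m must be positive")
            if row["peak_force_bw"] < row["mean_stance_force_bw"]:
                problems.append(
                    f"row {i}: peak force below stance-mean force"
                )
        if problems:
            raise ValueError(
                "invalid cohort table:\n" + "\n".join(problems[:20])
            )
        return data.reset_index(drop=True)

    # -- fitting ----------------------------------------------------------
    @property
    def mesh(self) -> ContactMesh:
        if self._mesh is None:
            self._mesh = build_mesh(self.geometry, self.material)
        return self._mesh

    def fit(
        self,
        outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
        alpha: float = 0.05,
        holm: bool = False,
    ) -> "CartilageLifetimeResults":
        """Run contact + failure for every trial and the statistics stage."""
        params = self.failure_params
        records = []
        curves: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
        curves_nr: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
        time_grid: np.ndarray | None = None
        failures: list[str] = []

        for i, row in self.data.iterrows():
            force_n = row["peak_force_bw"] * row["body_mass_kg"] * GRAVITY
            try:
                sol = solve_contact(
                    force_n, row["flexion_angle_deg"], mesh=self.mesh
                )
            except ContactSolverError as err:
                failures.append(f"row {i}: {err}")
                continue
            if params.volume_rule == "weibull":
                volume = sol.effective_volume(params.weibull_exponent)
            else:
                volume = sol.stressed_volume
            t_f = time_to_failure(
                sol.peak_strain, row["stride_length_m"], params
            )
            res = p_fail_with_repair(volume, t_f, params)
            rec = dict(row)
            rec.update(
                peak_stress_mpa=sol.peak_stress,
                peak_strain=sol.peak_strain,
                loaded_area_mm2=sol.loaded_area,
                stressed_volume_mm3=volume,
                axis_depth_mm=sol.axis_depth,
                cumulative_load_bw_per_m=cumulative_load(
                    row["mean_stance_force_bw"], row["stride_length_m"]
                ),
                daily_cycles=daily_loading_cycles(
                    row["stride_length_m"],
                    params.daily_distance,
                    count=params.cycle_count,
                ),
                time_to_failure_years=t_f,
                p_fail_with_repair_pct=100.0 * res.terminal_with_repair,
                p_fail_no_repair_pct=100.0 * res.terminal_no_repair,
            )
            records.append(rec)
            cond = row["condition"]
            curves[cond].append(res.p_fail_with_repair)
            curves_nr[cond].append(res.p_fail_no_repair)
            time_grid = res.time

        if failures:
            warnings.warn(
                f"{len(failures)} trial(s) quarantined by the contact "
                "solver:\n" + "\n".join(failures[:10]),
                RuntimeWarning,
                stacklevel=2,
            )
        if not records:
            raise ContactSolverError("every trial failed the contact solve")

        trial_results = pd.DataFrame(records)

        # trial -> participant mean within condition, then statistics
        available = [o for o in outcomes if o in trial_results.columns]
        participant_means = (
            trial_results.groupby(["participant_id", "condition"], sort=False)[
                list(available)
            ]
            .mean()
            .reset_index()
        )
        summary_rows = []
        for cond in CONDITIONS:
            sub = participant_means[participant_means["condition"] == cond]
            if sub.empty:
                continue
            for out in available:
                summary_rows.append(
                    dict(
                        condition=cond,
                        outcome=out,
                        mean=float(sub[out].mean()),
                        sd=float(sub[out].std(ddof=1)),
                        n_participants=int(sub.shape[0]),
                    )
                )
        condition_summary = pd.DataFrame(summary_rows)

        comparisons: list[ConditionComparison] = []
        n_conditions = participant_means["condition"].nunique()
        if n_conditions >= 2:
            for out in available:
                comparisons.extend(
                    fit_condition_model(
                        participant_means, out, alpha=alpha, holm=holm
                    )
                )

        failure_curves = self._mean_curves(time_grid, curves, curves_nr)
        meta = self._run_metadata()
        return CartilageLifetimeResults(
            model=self,
            trial_results=trial_results,
            participant_means=participant_means,
            condition_summary=condition_summary,
            comparisons=comparisons,
            failure_curves=failure_curves,
            quarantined=failures,
            metadata=meta,
        )

    @staticmethod
    def _mean_curves(time_grid, curves, curves_nr) -> pd.DataFrame:
        if time_grid is None:
            return pd.DataFrame()
        frames = {"time_years": time_grid}
        for cond in CONDITIONS:
            if curves[cond]:
                frames[f"{cond}_with_repair"] = np.mean(curves[cond], axis=0)
                frames[f"{cond}_no_repair"] = np.mean(curves_nr[cond], axis=0)
        return pd.DataFrame(frames)

    def _run_metadata(self) -> dict:
        config = dict(
            geometry=asdict(self.geometry),
            material=asdict(self.material),
            failure_params=asdict(self.failure_params),
        )
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return dict(
            config=config,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            n_trials=int(self.data.shape[0]),
        )


@dataclass
class CartilageLifetimeResults:
    """Fitted cohort results: per-trial mechanics, condition summaries,
    pairwise contrasts and mean failure-probability curves."""

    model: CartilageLifetimeModel = field(repr=False)
    trial_results: pd.DataFrame = field(repr=False)
    participant_means: pd.DataFrame = field(repr=False)
    condition_summary: pd.DataFrame = field(repr=False)
    comparisons: list[ConditionComparison] = field(repr=False)
    failure_curves: pd.DataFrame = field(repr=False)
    quarantined: list[str] = field(default_factory=list, repr=False)
    metadata: dict = field(default_factory=dict, repr=False)

    def condition_means(self, outcome: str) -> pd.Series:
        """Cohort mean of one outcome per condition (participant-weighted)."""
        sub = self.condition_summary[self.condition_summary["outcome"] == outcome]
        return sub.set_index("condition")["mean"]

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.comparisons])

    def summary(self) -> str:
        """Human-readable condition summary and contrast table."""
        lines = ["Medial tibiofemoral cartilage lifetime model", "=" * 46]
        lines.append(
            f"trials: {self.metadata.get('n_trials', '?')}  "
            f"config hash: {self.metadata.get('config_hash', '?')}"
        )
        lines.append("")
        lines.append("Condition means (SD) by outcome")
        lines.append("-" * 46)
        pivot_mean = self.condition_summary.pivot(
            index="outcome", columns="condition", values="mean"
        )
        pivot_sd = self.condition_summary.pivot(
            index="outcome", columns="condition", values="sd"
        )
        conds = [c for c in CONDITIONS if c in pivot_mean.columns]
        header = f"{'outcome':<28}" + "".join(f"{c:>18}" for c in conds)
        lines.append(header)
        for out in pivot_mean.index:
            cells = "".join(
                f"{pivot_mean.loc[out, c]:>10.3f} ({pivot_sd.loc[out, c]:.3f})"
                for c in conds
            )
            lines.append(f"{out:<28}{cells}")
        if self.comparisons:
            lines.append("")
            lines.append("Significant pairwise contrasts (p <= 0.05)")
            lines.append("-" * 46)
            any_sig = False
            for c in self.comparisons:
                if c.significant:
                    any_sig = True
                    lines.append(
                        f"{c.outcome}: {c.condition_a} vs {c.condition_b}  "
                        f"diff={c.mean_difference:+.3f}  p={c.p_value:.4f}  "
                        f"d={c.cohens_d:.2f}"
                    )
            if not any_sig:
                lines.append("(none)")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        """Write trial table, summaries, contrasts and curves as CSV/JSON."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.trial_results.to_csv(d / "trial_results.csv", index=False)
        self.participant_means.to_csv(d / "participant_means.csv", index=False)
        self.condition_summary.to_csv(d / "condition_summary.csv", index=False)
        self.comparisons_frame().to_csv(d / "comparisons.csv", index=False)
        if not self.failure_curves.empty:
            self.failure_curves.to_csv(d / "failure_curves.csv", index=False)
        (d / "run_metadata.json").write_text(
            json.dumps(self.metadata, indent=2, default=str)
        )

    def plot_failure_curves(self, ax=None):
        """Mean failure-probability time series per condition (with and
        without repair).  Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        t = self.failure_curves["time_years"]
        for cond in CONDITIONS:
            col = f"{cond}_with_repair"
            if col in self.failure_curves:
                ax.plot(t, 100 * self.failure_curves[col], label=f"{cond} (repair)")
                ax.plot(
                    t,
                    100 * self.failure_curves[f"{cond}_no_repair"],
                    linestyle="--",
                    alpha=0.5,
                    label=f"{cond} (no repair)",
                )
        ax.set_xlabel("time since skeletal maturity (years)")
        ax.set_ylabel("cartilage failure probability (%)")
        ax.legend(fontsize=8)
        return ax
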