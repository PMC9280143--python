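"""Model/Results interface over the interference-decision pipeline.

Follows the fit-and-summarise idiom: a model object is built from data
(scenario records or ERP amplitude triplets), ``fit()`` runs the closed-form
phase extraction and prediction, and the returned results object carries the
estimates, stability summaries, diagnostics and a ``summary()`` table.

The "fit" is deterministic — every phase is an exact inversion, and the
fitted phase is a fixed combination rule rather than an optimised free
parameter; the results object exists to organise estimates and fit
diagnostics, not to iterate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import pandas as pd

from .erp import ErpTriplet, erp_stability_report, read_electrode_table
from .exceptions import InsufficientDataError
from .fixtures import fixture_scenarios, fixture_triplets, load_fixture
from .scenario import (
    BinaryScenario,
    PhaseFitRule,
    PredictionResult,
    analyze,
    read_scenarios,
    scenarios_from_frame,
)
from .stability import mape, rmsd, summarize_phases

__all__ = [
    "InterferenceDecisionModel",
    "InterferenceDecisionResults",
    "ErpInterferenceModel",
    "ErpInterferenceResults",
]


class InterferenceDecisionModel:
    """Interference-phase decision model over a set of binary scenarios.

    Parameters
    ----------
    scenarios
        The experiments to analyse.
    rule
        Optional phase-combination rule applied to every scenario; by default
        each scenario uses its paradigm's preset.
    """

    def __init__(
        self,
        scenarios: Sequence[BinaryScenario],
        rule: Optional[PhaseFitRule] = None,
    ):
        self.scenarios = list(scenarios)
        if not self.scenarios:
            raise InsufficientDataError("at least one scenario is required")
        self.rule = rule

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rule: Optional[PhaseFitRule] = None):
        return cls(scenarios_from_frame(df), rule=rule)

    @classmethod
    def from_csv(cls, path, rule: Optional[PhaseFitRule] = None):
        return cls(read_scenarios(path), rule=rule)

    @classmethod
    def from_fixture(
        cls,
        table_id: str,
        input_set: Literal["printed", "fractions"] = "printed",
        rule: Optional[PhaseFitRule] = None,
    ):
        return cls(fixture_scenarios(load_fixture(table_id), input_set=input_set), rule=rule)

    def fit(self) -> "InterferenceDecisionResults":
        """Run the phase extraction and prediction for every scenario."""
        results = [analyze(s, rule=self.rule) for s in self.scenarios]
        return InterferenceDecisionResults(self, results)


class InterferenceDecisionResults:
    """Per-scenario phase estimates, predictions and fit diagnostics."""

    def __init__(self, model: InterferenceDecisionModel, results: list[PredictionResult]):
        self.model = model
        self.results = results

    @property
    def table(self) -> pd.DataFrame:
        """One row per scenario: theta_1..theta_4, theta_expt, theta_fit, p_fit."""
        return pd.DataFrame([r.to_dict() for r in self.results])

    def _observed(self) -> list[PredictionResult]:
        return [r for r in self.results if r.theta_expt is not None]

    def phase_summary(self, decimals: Optional[int] = 2) -> pd.DataFrame:
        """Mean, sample SD and CV of each phase column.

        ``decimals`` rounds phases to the stated precision before
        summarising (the convention under which published summary values
        reproduce); pass None for unrounded phases.
        """
        obs = self._observed()
        cols: dict[str, list[float]] = {
            f"theta{i}": [r.cell_table.theta(i) for r in self.results] for i in range(1, 5)
        }
        cols["theta_fit"] = [r.theta_fit_deg for r in self.results]
        if obs:
            cols["theta_expt"] = [r.theta_expt.theta_deg for r in obs]
        rows = []
        for name, values in cols.items():
            if decimals is not None:
                values = [round(v, decimals) for v in values]
            s = summarize_phases(values)
            rows.append(
                {"phase": name, "n": s.n, "mean": s.mean, "sample_sd": s.sample_sd, "cv": s.cv}
            )
        return pd.DataFrame(rows).set_index("phase")

    def rmsd(self, decimals: Optional[int] = 2, exclude: Sequence[str] = ()) -> float:
        """RMSD (population N) between experimental and fitted phases.

        ``exclude`` drops the named study ids — exclusion is always explicit
        configuration.
        """
        obs = [r for r in self._observed() if r.scenario.study_id not in set(exclude)]
        if not obs:
            raise InsufficientDataError("no scenarios with observed unknown-condition data")
        te = [r.theta_expt.theta_deg for r in obs]
        tf = [r.theta_fit_deg for r in obs]
        if decimals is not None:
            te = [round(v, decimals) for v in te]
            tf = [round(v, decimals) for v in tf]
        return rmsd(te, tf)

    def mape(self, denominator: str = "fitted", exclude: Sequence[str] = ()) -> float:
        """MAPE between observed and predicted unknown-condition probabilities."""
        obs = [r for r in self._observed() if r.scenario.study_id not in set(exclude)]
        if not obs:
            raise InsufficientDataError("no scenarios with observed unknown-condition data")
        return mape(
            [r.scenario.p_focal_unknown for r in obs],
            [r.p_fit.value for r in obs],
            denominator=denominator,
        )

    def warnings(self) -> list[str]:
        out = []
        for r in self.results:
            sid = r.scenario.study_id
            for i in range(1, 5):
                if r.cell_table.phase(i).clamped:
                    out.append(f"{sid}: theta{i} cosine clamped to boundary")
            if r.theta_expt is not None and r.theta_expt.clamped:
                out.append(f"{sid}: theta_expt cosine clamped to boundary")
            if r.p_fit.out_of_range:
                out.append(f"{sid}: p_fit outside [0, 1]")
        return out

    def summary(self) -> str:
        """Human-readable results table plus stability summary."""
        df = self.table
        num_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
        shown = df.copy()
        shown[num_cols] = shown[num_cols].round(2)
        # flag columns earn their width only when something was flagged
        for col in [c for c in shown.columns if c.endswith("_clamped") or c.endswith("_out_of_range")]:
            if not shown[col].any():
                shown = shown.drop(columns=[col])
        lines = [
            "Interference decision model results",
            f"  scenarios: {len(self.results)}",
            "",
            shown.to_string(index=False),
            "",
            "Phase stability (phases rounded to 2 dp):",
            self.phase_summary().round(2).to_string(),
        ]
        obs = self._observed()
        if obs:
            lines.append("")
            lines.append(f"RMSD(theta_expt, theta_fit) = {self.rmsd():.2f} deg (n={len(obs)})")
            lines.append(f"MAPE(observed, fitted; fitted denominator) = {self.mape():.2f}")
        w = self.warnings()
        if w:
            lines.append("")
            lines.append("Warnings:")
            lines.extend(f"  - {msg}" for msg in w)
        return "\n".join(lines)


class ErpInterferenceModel:
    """Interference-phase model over ERP amplitude triplets."""

    def __init__(self, triplets: Sequence[ErpTriplet]):
        self.triplets = list(triplets)
        if len(self.triplets) < 2:
            raise InsufficientDataError("at least two electrodes are required")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        return cls(
            [
                ErpTriplet(
                    electrode=str(r["electrode"]),
                    amplitude_pos=r["amplitude_pos"],
                    amplitude_neg=r["amplitude_neg"],
                    amplitude_neutral=r["amplitude_neutral"],
                )
                for _, r in df.iterrows()
            ]
        )

    @classmethod
    def from_csv(cls, path):
        return cls(read_electrode_table(path))

    @classmethod
    def from_fixture(cls, table_id: str):
        return cls(fixture_triplets(load_fixture(table_id)))

    def fit(self) -> "ErpInterferenceResults":
        return ErpInterferenceResults(self, erp_stability_report(self.triplets))


class ErpInterferenceResults:
    """Electrode-wise phases and the phase-vs-amplitude stability comparison."""

    def __init__(self, model: ErpInterferenceModel, report):
        self.model = model
        self.report = report

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "electrode": t.electrode,
                    "amplitude_pos": t.amplitude_pos,
                    "amplitude_neg": t.amplitude_neg,
                    "amplitude_neutral": t.amplitude_neutral,
                    "theta": p.theta_deg,
                    "clamped": p.clamped,
                }
                for t, p in zip(self.model.triplets, self.report.phase_results)
            ]
        )

    @property
    def phase_cv(self) -> float:
        return self.report.phases.cv

    @property
    def amplitude_cvs(self) -> dict[str, float]:
        return {name: s.cv for name, s in self.report.amplitudes.items()}

    @property
    def phase_more_stable(self) -> bool:
        return self.report.phase_more_stable

    def summary(self) -> str:
        shown = self.table.copy()
        shown["theta"] = shown["theta"].round(2)
        amp = ", ".join(f"{k}={v:.2f}" for k, v in self.amplitude_cvs.items())
        return "\n".join(
            [
                "ERP interference-phase results",
                f"  electrodes: {len(self.model.triplets)}",
                "",
                shown.to_string(index=False),
                "",
                f"phase: {self.report.phases}",
                f"phase CV = {self.phase_cv:.2f}; amplitude CVs: {amp}",
                f"phase more stable than every amplitude column: {self.phase_more_stable}",
            ]
        )
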