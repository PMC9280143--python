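"""Bundled reference tables and table-reproduction routines.

Six small CSVs ship with the package: three electrode tables (mean ERP
amplitudes per stimulus class) and three behavioral tables (categorization
decision, two-stage gambling, prisoner's dilemma).  Each stores the input
columns exactly as published (two-decimal probabilities, amplitudes in
microvolts) together with the published derived columns (theta_1..theta_4,
theta_expt, theta_fit, p_fit, or theta per electrode).  Derived columns are
retained for comparison only and are never fed back into any computation.

``reproduce_table`` recomputes every derived column from the inputs and
compares cell by cell against the published values.  Agreement is exact at
the printed precision for the categorization and gambling tables, with one
known exception (G2's p_fit, evidently a misprint).  The prisoner's-dilemma
inputs were evidently rounded from fractions with denominator 30 before
printing, so printed-input recomputation drifts by up to ~1.7 degrees in the
most sensitive cells; reconstructing the fractions (``input_set="fractions"``)
brings every phase cell within 0.1 degrees of print except PD2's theta_expt
(printed 101.29, recomputed 101.04; the printed-input recomputation gives
101.39, suggesting a transposed digit).  The exception lists are frozen here
and asserted exactly by the test suite — a new mismatch is an error, not a
tolerance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .erp import AMPLITUDE_COLUMNS, ErpTriplet, erp_stability_report
from .exceptions import ConfigurationError
from .scenario import BinaryScenario, analyze
from .stability import StabilitySummary, mape, rmsd, summarize_phases

__all__ = [
    "TABLE_IDS",
    "FixtureTable",
    "ReproductionReport",
    "load_fixture",
    "fixture_scenarios",
    "fixture_triplets",
    "reproduce_table",
    "KNOWN_EXCEPTIONS",
]

TABLE_IDS = (
    "erp_n270",
    "erp_p300_distance",
    "erp_p300_intention",
    "categorization",
    "gambling",
    "prisoners_dilemma",
)

PHASE_COLUMNS = ("theta_expt", "theta1", "theta2", "theta3", "theta4", "theta_fit")
DERIVED_COLUMNS = PHASE_COLUMNS + ("p_fit",)

#: Per-table metadata: provenance stays as opaque study labels; the
#: (positive, negative, neutral) stimulus-class assignment of each ERP table
#: is data, not code.
_META: Mapping[str, dict] = {
    "erp_n270": {
        "kind": "erp",
        "component": "N270",
        "classes": ("task-relevant conflict", "task-irrelevant conflict", "conjunction conflicts"),
    },
    "erp_p300_distance": {
        "kind": "erp",
        "component": "P300",
        "classes": ("far outcome", "near outcome", "medium outcome"),
    },
    "erp_p300_intention": {
        "kind": "erp",
        "component": "P300",
        "classes": ("kind action", "hostile action", "non-interactive action"),
    },
    "categorization": {
        "kind": "behavioral",
        "condition_labels": ("good", "bad"),
        "decision_labels": ("withdraw", "attack"),
        "focal_decision": "alternative",  # the published column is p(attack|...)
        "input_columns": ("p_attack_good", "p_attack_bad", "p_good", "p_attack_alone"),
    },
    "gambling": {
        "kind": "behavioral",
        "condition_labels": ("win", "lose"),
        "decision_labels": ("play again", "stop"),
        "focal_decision": "reference",
        "input_columns": ("p_again_win", "p_again_lose", "p_win", "p_again_unknown"),
    },
    "prisoners_dilemma": {
        "kind": "behavioral",
        "condition_labels": ("known defect", "known cooperate"),
        "decision_labels": ("defect", "cooperate"),
        "focal_decision": "reference",
        "input_columns": ("p_defect_kd", "p_defect_kc", "p_kd", "p_defect_unknown"),
        # group sizes of the source experiments; inputs were evidently
        # printed as round(p * 30) / 30
        "fraction_denominator": 30,
    },
}

#: Cells known not to reproduce, frozen per (table_id, input_set); the test
#: suite asserts these sets exactly.
KNOWN_EXCEPTIONS: Mapping[tuple[str, str], frozenset[tuple[str, str]]] = {
    ("categorization", "printed"): frozenset(),
    # printed 0.40 but the row's own printed theta_fit=106.91 gives 0.45
    ("gambling", "printed"): frozenset({("G2", "p_fit")}),
    # phase cells drifting > 0.5 deg when the rounded printed inputs are used
    ("prisoners_dilemma", "printed"): frozenset(
        {
            ("PD4", "theta2"),
            ("PD4", "theta_fit"),
            ("PD5", "theta2"),
            ("PD5", "theta4"),
            ("PD6", "theta4"),
        }
    ),
    # printed 101.29; fraction inputs give 101.04, printed inputs 101.39
    ("prisoners_dilemma", "fractions"): frozenset({("PD2", "theta_expt")}),
}

#: How recomputed cells are compared with print, per (table_id, input_set):
#: ("round", decimals) means equality after rounding to the printed
#: precision; ("tol", phase_tol, prob_tol) means absolute tolerances for
#: phase and probability cells (used where inputs are known to be rounded).
_COMPARISON: Mapping[tuple[str, str], tuple] = {
    ("categorization", "printed"): ("round", 2),
    ("gambling", "printed"): ("round", 2),
    ("prisoners_dilemma", "printed"): ("tol", 0.5, 0.02),
    ("prisoners_dilemma", "fractions"): ("tol", 0.1, 0.005),
}


@dataclass(frozen=True)
class FixtureTable:
    """One bundled table: inputs as printed plus printed derived columns."""

    table_id: str
    data: pd.DataFrame
    meta: dict

    @property
    def kind(self) -> str:
        return self.meta["kind"]

    @property
    def n_rows(self) -> int:
        return len(self.data)


def load_fixture(table_id: str) -> FixtureTable:
    """Load and validate one bundled table by id."""
    if table_id not in TABLE_IDS:
        raise ConfigurationError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
    path = importlib.resources.files("wavedecision.data") / f"{table_id}.csv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    meta = dict(_META[table_id])
    if meta["kind"] == "erp":
        if (df[list(AMPLITUDE_COLUMNS)] < 0).any().any():
            raise ConfigurationError(f"{table_id}: negative amplitude in fixture")
    else:
        prob_cols = [c for c in df.columns if c.startswith("p_")]
        probs = df[prob_cols]
        if ((probs < 0) | (probs > 1)).any().any():
            raise ConfigurationError(f"{table_id}: probability outside [0, 1] in fixture")
    return FixtureTable(table_id=table_id, data=df, meta=meta)


def _reconstruct_fraction(p: float, denominator: int) -> float:
    """Nearest fraction k/denominator to a printed probability."""
    return round(p * denominator) / denominator


def fixture_scenarios(
    fixture: FixtureTable,
    input_set: Literal["printed", "fractions"] = "printed",
) -> list[BinaryScenario]:
    """Convert a behavioral fixture's rows into :class:`BinaryScenario`.

    ``input_set="fractions"`` replaces every printed probability with the
    nearest fraction over the table's group-size denominator (available only
    where the metadata records one).
    """
    if fixture.kind != "behavioral":
        raise ConfigurationError(f"{fixture.table_id} is not a behavioral table")
    if input_set not in ("printed", "fractions"):
        raise ConfigurationError(f"input_set must be 'printed' or 'fractions', got {input_set!r}")
    denom = fixture.meta.get("fraction_denominator")
    if input_set == "fractions" and denom is None:
        raise ConfigurationError(
            f"{fixture.table_id} has no recorded fraction denominator; "
            "fraction-reconstructed inputs are unavailable"
        )

    c_ref_pos, c_ref_neg, c_pos, c_unknown = fixture.meta["input_columns"]
    focal = fixture.meta["focal_decision"]
    scenarios = []
    for _, row in fixture.data.iterrows():
        vals = {k: float(row[k]) for k in (c_ref_pos, c_ref_neg, c_pos, c_unknown)}
        if input_set == "fractions":
            # condition marginals are design constants (0.5/0.5), not sampled
            vals[c_ref_pos] = _reconstruct_fraction(vals[c_ref_pos], denom)
            vals[c_ref_neg] = _reconstruct_fraction(vals[c_ref_neg], denom)
            vals[c_unknown] = _reconstruct_fraction(vals[c_unknown], denom)
        if fixture.table_id == "categorization":
            paradigm = (
                "categorization_wide" if row["face_type"] == "W" else "categorization_narrow"
            )
            # published columns are p(attack|...); the reference decision is withdraw
            p_ref_pos = 1.0 - vals[c_ref_pos]
            p_ref_neg = 1.0 - vals[c_ref_neg]
        else:
            paradigm = "gambling" if fixture.table_id == "gambling" else "prisoners_dilemma"
            p_ref_pos = vals[c_ref_pos]
            p_ref_neg = vals[c_ref_neg]
        scenarios.append(
            BinaryScenario(
                study_id=str(row["study_id"]),
                paradigm=paradigm,
                p_cond_pos=vals[c_pos],
                p_ref_given_pos=p_ref_pos,
                p_ref_given_neg=p_ref_neg,
                p_focal_unknown=vals[c_unknown],
                focal_decision=focal,
                condition_labels=fixture.meta["condition_labels"],
                decision_labels=fixture.meta["decision_labels"],
            )
        )
    return scenarios


def fixture_triplets(fixture: FixtureTable) -> list[ErpTriplet]:
    """Convert an ERP fixture's rows into :class:`ErpTriplet`."""
    if fixture.kind != "erp":
        raise ConfigurationError(f"{fixture.table_id} is not an ERP table")
    return [
        ErpTriplet(
            electrode=str(row["electrode"]),
            amplitude_pos=row["amplitude_pos"],
            amplitude_neg=row["amplitude_neg"],
            amplitude_neutral=row["amplitude_neutral"],
        )
        for _, row in fixture.data.iterrows()
    ]


@dataclass(frozen=True)
class ReproductionReport:
    """Cell-by-cell comparison of recomputed vs published derived columns.

    ``mismatches`` holds every (study_id/electrode, column) cell that fails
    the table's comparison policy; ``unexpected_mismatches`` and
    ``missing_expected`` relate that set to the frozen exception registry, so
    ``ok`` means the recomputation disagrees with print *exactly* where it is
    known to.
    """

    table_id: str
    input_set: str
    recomputed: pd.DataFrame
    printed: pd.DataFrame
    diffs: pd.DataFrame
    mismatches: tuple[tuple[str, str], ...]
    known_exceptions: frozenset[tuple[str, str]]
    summaries: dict
    warnings: tuple[str, ...] = ()

    @property
    def unexpected_mismatches(self) -> tuple[tuple[str, str], ...]:
        return tuple(m for m in self.mismatches if m not in self.known_exceptions)

    @property
    def missing_expected(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.known_exceptions - set(self.mismatches)))

    @property
    def ok(self) -> bool:
        return not self.unexpected_mismatches and not self.missing_expected

    def to_dict(self) -> dict:
        return {
            "table_id": self.table_id,
            "input_set": self.input_set,
            "recomputed": self.recomputed.to_dict(orient="records"),
            "printed": self.printed.to_dict(orient="records"),
            "mismatches": [list(m) for m in self.mismatches],
            "known_exceptions": sorted(list(m) for m in self.known_exceptions),
            "unexpected_mismatches": [list(m) for m in self.unexpected_mismatches],
            "missing_expected": [list(m) for m in self.missing_expected],
            "ok": self.ok,
            "summaries": self.summaries,
            "warnings": list(self.warnings),
        }


def _summary_dict(s: StabilitySummary) -> dict:
    return {
        "n": s.n,
        "mean": s.mean,
        "sample_sd": s.sample_sd,
        "cv": s.cv,
    }


def _behavioral_report(
    fixture: FixtureTable,
    input_set: str,
    mape_denominator: str,
    phase_decimals: int = 2,
) -> ReproductionReport:
    scenarios = fixture_scenarios(fixture, input_set=input_set)
    results = [analyze(s) for s in scenarios]
    rec = pd.DataFrame(
        [
            {
                "study_id": r.scenario.study_id,
                "theta_expt": r.theta_expt.theta_deg,
                "theta1": r.cell_table.theta(1),
                "theta2": r.cell_table.theta(2),
                "theta3": r.cell_table.theta(3),
                "theta4": r.cell_table.theta(4),
                "theta_fit": r.theta_fit_deg,
                "p_fit": r.p_fit.value,
            }
            for r in results
        ]
    )
    printed = fixture.data[["study_id", *DERIVED_COLUMNS]].copy()
    diffs = rec[list(DERIVED_COLUMNS)] - printed[list(DERIVED_COLUMNS)]
    diffs.insert(0, "study_id", rec["study_id"])

    policy = _COMPARISON[(fixture.table_id, input_set)]
    mismatches = []
    for i in range(len(rec)):
        sid = rec.loc[i, "study_id"]
        for col in DERIVED_COLUMNS:
            r, p = rec.loc[i, col], printed.loc[i, col]
            if policy[0] == "round":
                bad = round(float(r), policy[1]) != round(float(p), policy[1])
            else:
                tol = policy[2] if col == "p_fit" else policy[1]
                bad = abs(float(r) - float(p)) > tol
            if bad:
                mismatches.append((sid, col))

    warnings = []
    for r in results:
        for i in range(1, 5):
            if r.cell_table.phase(i).clamped:
                warnings.append(f"{r.scenario.study_id}: theta{i} cosine clamped to boundary")
        if r.theta_expt is not None and r.theta_expt.clamped:
            warnings.append(f"{r.scenario.study_id}: theta_expt cosine clamped to boundary")
        if r.p_fit.out_of_range:
            warnings.append(f"{r.scenario.study_id}: p_fit outside [0, 1]")

    # summary statistics: phases at printed precision (matching how the
    # published summaries were evidently computed), MAPE on unrounded p_fit
    if fixture.table_id == "categorization":
        groups = {
            "wide": [r for r in results if r.scenario.paradigm == "categorization_wide"],
            "narrow": [r for r in results if r.scenario.paradigm == "categorization_narrow"],
        }
    else:
        groups = {"all": results}
    summaries: dict = {}
    for name, rs in groups.items():
        te = [round(r.theta_expt.theta_deg, phase_decimals) for r in rs]
        tf = [round(r.theta_fit_deg, phase_decimals) for r in rs]
        g: dict = {
            "n": len(rs),
            "rmsd_expt_vs_fit": rmsd(te, tf),
            "mape": mape(
                [r.scenario.p_focal_unknown for r in rs],
                [r.p_fit.value for r in rs],
                denominator=mape_denominator,
            ),
            "theta_expt": _summary_dict(summarize_phases(te)),
            "theta_fit": _summary_dict(summarize_phases(tf)),
        }
        for i in range(1, 5):
            col = [round(r.cell_table.theta(i), phase_decimals) for r in rs]
            g[f"theta{i}"] = _summary_dict(summarize_phases(col))
        summaries[name] = g

    return ReproductionReport(
        table_id=fixture.table_id,
        input_set=input_set,
        recomputed=rec,
        printed=printed,
        diffs=diffs,
        mismatches=tuple(mismatches),
        known_exceptions=KNOWN_EXCEPTIONS[(fixture.table_id, input_set)],
        summaries=summaries,
        warnings=tuple(warnings),
    )


def _erp_report(fixture: FixtureTable, phase_tol: float = 0.6) -> ReproductionReport:
    triplets = fixture_triplets(fixture)
    report = erp_stability_report(triplets)
    rec = pd.DataFrame(
        {
            "electrode": [t.electrode for t in triplets],
            "theta": [p.theta_deg for p in report.phase_results],
        }
    )
    printed = fixture.data[["electrode", "theta_printed"]].rename(
        columns={"theta_printed": "theta"}
    )
    diffs = pd.DataFrame(
        {"electrode": rec["electrode"], "theta": rec["theta"] - printed["theta"]}
    )
    # published ERP phases come from unrounded source amplitudes, so the
    # comparison is a tolerance, not printed-precision equality
    mismatches = tuple(
        (rec.loc[i, "electrode"], "theta")
        for i in range(len(rec))
        if abs(diffs.loc[i, "theta"]) > phase_tol
    )
    summaries = {
        "phase_cv": report.phases.cv,
        "phase": _summary_dict(report.phases),
        "amplitude_cvs": {c: report.amplitudes[c].cv for c in AMPLITUDE_COLUMNS},
        "phase_more_stable": report.phase_more_stable,
        "max_abs_phase_diff": float(diffs["theta"].abs().max()),
    }
    return ReproductionReport(
        table_id=fixture.table_id,
        input_set="printed",
        recomputed=rec,
        printed=printed,
        diffs=diffs,
        mismatches=mismatches,
        known_exceptions=frozenset(),
        summaries=summaries,
    )


def reproduce_table(
    table_id: str,
    input_set: Literal["printed", "fractions"] = "printed",
    mape_denominator: str = "fitted",
) -> ReproductionReport:
    """Recompute a bundled table's derived columns and compare with print.

    Behavioral tables are recomputed through the full scenario pipeline
    (cell phases, experimental phase, preset fit rule, predicted
    probability); ERP tables through the amplitude-triplet inversion.
    """
    fixture = load_fixture(table_id)
    if fixture.kind == "erp":
        if input_set != "printed":
            raise ConfigurationError("ERP tables have no alternative input set")
        return _erp_report(fixture)
    return _behavioral_report(fixture, input_set, mape_denominator)
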