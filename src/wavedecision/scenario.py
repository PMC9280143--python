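"""Two-condition / two-decision behavioral experiments.

A :class:`BinaryScenario` holds the probabilities a disjunction-effect
experiment reports: the condition marginal p(C+), the two conditional
decision probabilities p(d_ref|C+), p(d_ref|C-), and (optionally) the
observed probability of the focal decision when the condition is unknown.

From those, the module derives

* the four known-condition cell phases theta_1..theta_4, one per
  (decision, condition) cell, by inverting the interference combination of
  the cell's joint probability against its two marginals;
* the experimental phase theta_expt, by inverting the observed
  unknown-condition probability against the two focal-decision joints;
* a fitted phase theta_fit from a per-paradigm combination rule over the
  cell phases; and
* the predicted unknown-condition probability at theta_fit.

Cell-index convention
---------------------
The cell labels that reproduce the published phase tables are

    theta_1 = (reference, positive)    theta_2 = (alternative, positive)
    theta_3 = (reference, negative)    theta_4 = (alternative, negative)

where the *reference* decision is withdraw (categorization), play-again
(gambling) or defect (prisoner's dilemma).  Note this is an empirical
mapping: the four-cell system is sometimes written with the cells keyed by
(decision sign, condition sign) instead, but that labelling does not
reproduce the published tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import CombinedProbability, PhaseResult, invert_phase, two_wave_probability
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
    MissingObservationError,
)

__all__ = [
    "PARADIGMS",
    "BinaryScenario",
    "CellPhaseTable",
    "PhaseFitRule",
    "PredictionResult",
    "cell_joints",
    "known_condition_phases",
    "experimental_phase",
    "fitted_phase",
    "predict_unknown",
    "analyze",
    "read_scenarios",
    "write_scenarios",
    "preset_rule",
    "min_conditional_rule",
]

PARADIGMS = (
    "categorization_wide",
    "categorization_narrow",
    "gambling",
    "prisoners_dilemma",
    "custom",
)

DECISIONS = ("reference", "alternative")
CONDITIONS = ("positive", "negative")

#: cell index -> (decision, condition), the mapping that reproduces the
#: published theta_1..theta_4 columns.
CELL_INDEX: Mapping[int, tuple[str, str]] = {
    1: ("reference", "positive"),
    2: ("alternative", "positive"),
    3: ("reference", "negative"),
    4: ("alternative", "negative"),
}


def _check_probability(name: str, x: float, allow_none: bool = False):
    if x is None:
        if allow_none:
            return None
        raise InvalidInputError(f"{name} is required")
    x = float(x)
    if not math.isfinite(x) or not 0.0 <= x <= 1.0:
        raise InvalidInputError(f"{name} must be a probability in [0, 1], got {x!r}")
    return x


@dataclass(frozen=True)
class BinaryScenario:
    """One two-condition / two-decision experiment.

    Parameters
    ----------
    study_id
        Free-text identifier.
    paradigm
        One of :data:`PARADIGMS`; selects the default phase-combination rule.
    p_cond_pos
        Condition marginal p(C+); p(C-) = 1 - p(C+).
    p_ref_given_pos, p_ref_given_neg
        Conditional probabilities of the *reference* decision under each
        known condition.  The alternative decision takes the complements.
    p_focal_unknown
        Observed probability of the focal decision under the unknown
        condition, if the experiment measured it.
    focal_decision
        Which decision ``p_focal_unknown`` (and the prediction) refers to:
        ``"reference"`` or ``"alternative"``.
    condition_labels, decision_labels
        Human-readable (positive, negative) and (reference, alternative)
        label pairs, carried through to reports.
    n_subjects
        Optional per-condition group size.
    """

    study_id: str
    paradigm: str
    p_cond_pos: float
    p_ref_given_pos: float
    p_ref_given_neg: float
    p_focal_unknown: Optional[float] = None
    focal_decision: str = "reference"
    condition_labels: tuple[str, str] = ("positive", "negative")
    decision_labels: tuple[str, str] = ("reference", "alternative")
    n_subjects: Optional[int] = None

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ConfigurationError(
                f"unknown paradigm {self.paradigm!r}; expected one of {PARADIGMS}"
            )
        if self.focal_decision not in DECISIONS:
            raise InvalidInputError(
                f"focal_decision must be 'reference' or 'alternative', got {self.focal_decision!r}"
            )
        for name in ("p_cond_pos", "p_ref_given_pos", "p_ref_given_neg"):
            object.__setattr__(self, name, _check_probability(name, getattr(self, name)))
        object.__setattr__(
            self,
            "p_focal_unknown",
            _check_probability("p_focal_unknown", self.p_focal_unknown, allow_none=True),
        )
        if self.n_subjects is not None and int(self.n_subjects) < 1:
            raise InvalidInputError(f"n_subjects must be >= 1, got {self.n_subjects!r}")

    @property
    def p_cond_neg(self) -> float:
        return 1.0 - self.p_cond_pos

    def conditional(self, decision: str, condition: str) -> float:
        """p(decision | condition) for any of the four cells."""
        p_ref = self.p_ref_given_pos if condition == "positive" else self.p_ref_given_neg
        return p_ref if decision == "reference" else 1.0 - p_ref

    def condition_marginal(self, condition: str) -> float:
        return self.p_cond_pos if condition == "positive" else self.p_cond_neg


@dataclass(frozen=True)
class CellJoints:
    """Joint probabilities p(d, c) and decision marginals of a scenario."""

    joints: Mapping[tuple[str, str], float]
    decision_marginals: Mapping[str, float]

    def joint(self, decision: str, condition: str) -> float:
        return self.joints[(decision, condition)]

    def focal_joints(self, focal_decision: str) -> tuple[float, float]:
        """(positive, negative) joints of the focal decision."""
        return (
            self.joints[(focal_decision, "positive")],
            self.joints[(focal_decision, "negative")],
        )


@dataclass(frozen=True)
class CellPhaseTable:
    """The four known-condition cell phases with the quantities they came from."""

    phases: Mapping[int, PhaseResult]
    joints: CellJoints
    scenario: BinaryScenario

    def theta(self, index: int) -> float:
        return self.phases[index].theta_deg

    def phase(self, index: int) -> PhaseResult:
        return self.phases[index]

    @property
    def any_clamped(self) -> bool:
        return any(p.clamped for p in self.phases.values())


@dataclass(frozen=True)
class PhaseFitRule:
    """A phase-combination rule producing theta_fit from cell phases.

    ``form`` is ``"sum_complement"`` (theta_fit = 360 - (theta_a + theta_b),
    two cells) or ``"half_complement"`` (theta_fit = (360 - theta_a)/2, one
    cell).  ``cells`` names the feeding cell indices (1..4).
    """

    form: str
    cells: tuple[int, ...]
    preset: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form == "sum_complement":
            n = 2
        elif self.form == "half_complement":
            n = 1
        else:
            raise ConfigurationError(f"unknown rule form {self.form!r}")
        if len(self.cells) != n or any(c not in CELL_INDEX for c in self.cells):
            raise ConfigurationError(
                f"rule form {self.form!r} needs {n} cell index(es) in 1..4, got {self.cells!r}"
            )


#: Per-paradigm presets.  The wide-face rule combines the two
#: positive-condition cells; the narrow-face rule the (reference, positive)
#: and (alternative, negative) cells; both disjunction paradigms halve the
#: complement of the fixed (alternative, positive) cell.
PRESET_RULES: Mapping[str, PhaseFitRule] = {
    "categorization_wide": PhaseFitRule("sum_complement", (1, 2), "categorization_wide"),
    "categorization_narrow": PhaseFitRule("sum_complement", (1, 4), "categorization_narrow"),
    "gambling": PhaseFitRule("half_complement", (2,), "gambling"),
    "prisoners_dilemma": PhaseFitRule("half_complement", (2,), "prisoners_dilemma"),
}


def preset_rule(paradigm: str) -> PhaseFitRule:
    """The default phase-combination rule for a paradigm."""
    try:
        return PRESET_RULES[paradigm]
    except KeyError:
        raise ConfigurationError(
            f"no preset rule for paradigm {paradigm!r}; supply an explicit PhaseFitRule"
        ) from None


def min_conditional_rule(scenario: BinaryScenario) -> PhaseFitRule:
    """Alternative half-complement rule on the minimum-conditional cell.

    Selects the (decision, condition) cell whose conditional probability
    p(d|c) is smallest — the riskiest choice — instead of the fixed
    (alternative, positive) cell.  Off by default because the fixed-cell
    reading is what reproduces the published prisoner's-dilemma fits.
    """
    idx = min(
        CELL_INDEX,
        key=lambda i: scenario.conditional(*CELL_INDEX[i]),
    )
    return PhaseFitRule("half_complement", (idx,), "min_conditional")


@dataclass(frozen=True)
class PredictionResult:
    """Full analysis of one scenario: phases, fitted phase, prediction."""

    scenario: BinaryScenario
    cell_table: CellPhaseTable
    theta_fit_deg: float
    p_fit: CombinedProbability
    theta_expt: Optional[PhaseResult] = None
    rule: Optional[PhaseFitRule] = None

    @property
    def residual_deg(self) -> Optional[float]:
        """theta_expt - theta_fit, or None in prediction-only mode."""
        if self.theta_expt is None:
            return None
        return self.theta_expt.theta_deg - self.theta_fit_deg

    def to_dict(self) -> dict:
        d = {
            "study_id": self.scenario.study_id,
            "paradigm": self.scenario.paradigm,
            "theta_expt": None if self.theta_expt is None else self.theta_expt.theta_deg,
            "theta_expt_clamped": None if self.theta_expt is None else self.theta_expt.clamped,
            "theta_fit": self.theta_fit_deg,
            "p_fit": self.p_fit.value,
            "p_fit_out_of_range": self.p_fit.out_of_range,
            "residual": self.residual_deg,
            "p_observed_unknown": self.scenario.p_focal_unknown,
        }
        for i in range(1, 5):
            pr = self.cell_table.phase(i)
            d[f"theta{i}"] = pr.theta_deg
            d[f"theta{i}_clamped"] = pr.clamped
        return d


def cell_joints(scenario: BinaryScenario) -> CellJoints:
    """Joint probabilities p(d, c) = p(c) * p(d|c) and decision marginals.

    The four joints sum to one; each decision marginal is the sum of its two
    joints (law of total probability bookkeeping).
    """
    joints = {
        (d, c): scenario.condition_marginal(c) * scenario.conditional(d, c)
        for d in DECISIONS
        for c in CONDITIONS
    }
    marginals = {d: joints[(d, "positive")] + joints[(d, "negative")] for d in DECISIONS}
    return CellJoints(joints=joints, decision_marginals=marginals)


def known_condition_phases(scenario: BinaryScenario) -> CellPhaseTable:
    """Invert the four known-condition cell phases.

    Each cell phase solves
    ``p(d, c) = p(d) + p(c) + 2*sqrt(p(d)*p(c))*cos(theta)``
    for theta, i.e. the joint is treated as the interference of the decision
    and condition marginals.

    Raises
    ------
    DegenerateInputError
        If a decision or condition marginal is zero for some cell.
    """
    joints = cell_joints(scenario)
    phases: dict[int, PhaseResult] = {}
    for idx, (d, c) in CELL_INDEX.items():
        p_d = joints.decision_marginals[d]
        p_c = scenario.condition_marginal(c)
        try:
            phases[idx] = invert_phase(joints.joint(d, c), p_d, p_c)
        except DegenerateInputError as err:
            raise DegenerateInputError(
                f"{scenario.study_id}: cell theta_{idx} ({d}, {c}) is degenerate: {err}"
            ) from err
    return CellPhaseTable(phases=phases, joints=joints, scenario=scenario)


def experimental_phase(scenario: BinaryScenario) -> PhaseResult:
    """Invert the unknown-condition phase from the observed probability.

    Solves ``p(focal|unknown) = j+ + j- + 2*sqrt(j+ j-)*cos(theta)`` where
    ``j+, j-`` are the focal decision's joints under the two known
    conditions.

    Raises
    ------
    MissingObservationError
        If the scenario carries no observed unknown-condition probability.
    """
    if scenario.p_focal_unknown is None:
        raise MissingObservationError(
            f"{scenario.study_id}: no observed unknown-condition probability"
        )
    j_pos, j_neg = cell_joints(scenario).focal_joints(scenario.focal_decision)
    return invert_phase(scenario.p_focal_unknown, j_pos, j_neg)


def fitted_phase(table: CellPhaseTable, rule: PhaseFitRule) -> float:
    """Apply a phase-combination rule to the cell phases."""
    thetas = [table.theta(i) for i in rule.cells]
    if rule.form == "sum_complement":
        return 360.0 - (thetas[0] + thetas[1])
    return (360.0 - thetas[0]) / 2.0


def predict_unknown(scenario: BinaryScenario, theta_deg: float) -> CombinedProbability:
    """Predicted focal-decision probability under the unknown condition."""
    j_pos, j_neg = cell_joints(scenario).focal_joints(scenario.focal_decision)
    return two_wave_probability(j_pos, j_neg, theta_deg)


def analyze(
    scenario: BinaryScenario,
    rule: Optional[PhaseFitRule] = None,
) -> PredictionResult:
    """Chain the full pipeline for one scenario.

    Computes cell joints, the four cell phases, the fitted phase under
    ``rule`` (the paradigm preset when omitted) and the predicted
    unknown-condition probability.  The experimental phase and residual are
    included when the scenario has an observed unknown-condition probability;
    otherwise the result is prediction-only.
    """
    if rule is None:
        rule = preset_rule(scenario.paradigm)
    table = known_condition_phases(scenario)
    theta_fit = fitted_phase(table, rule)
    p_fit = predict_unknown(scenario, theta_fit)
    theta_expt = None
    if scenario.p_focal_unknown is not None:
        theta_expt = experimental_phase(scenario)
    return PredictionResult(
        scenario=scenario,
        cell_table=table,
        theta_fit_deg=theta_fit,
        p_fit=p_fit,
        theta_expt=theta_expt,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# Tabular scenario I/O (comma-separated, point decimal, mandatory header)

SCENARIO_COLUMNS = [
    "study_id",
    "paradigm",
    "p_cond_pos",
    "p_ref_given_pos",
    "p_ref_given_neg",
    "p_focal_unknown",
    "focal_decision",
    "n_subjects",
]


def scenarios_to_frame(scenarios: Sequence[BinaryScenario]) -> pd.DataFrame:
    rows = [
        {
            "study_id": s.study_id,
            "paradigm": s.paradigm,
            "p_cond_pos": s.p_cond_pos,
            "p_ref_given_pos": s.p_ref_given_pos,
            "p_ref_given_neg": s.p_ref_given_neg,
            "p_focal_unknown": s.p_focal_unknown,
            "focal_decision": s.focal_decision,
            "n_subjects": s.n_subjects,
        }
        for s in scenarios
    ]
    return pd.DataFrame(rows, columns=SCENARIO_COLUMNS)


def scenarios_from_frame(df: pd.DataFrame) -> list[BinaryScenario]:
    missing = [c for c in SCENARIO_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise InvalidInputError(f"scenario table is missing columns: {missing}")
    out = []
    for i, row in df.iterrows():
        p_unknown = row.get("p_focal_unknown")
        if p_unknown is not None and pd.isna(p_unknown):
            p_unknown = None
        n = row.get("n_subjects")
        if n is not None and pd.isna(n):
            n = None
        try:
            out.append(
                BinaryScenario(
                    study_id=str(row["study_id"]),
                    paradigm=str(row["paradigm"]),
                    p_cond_pos=row["p_cond_pos"],
                    p_ref_given_pos=row["p_ref_given_pos"],
                    p_ref_given_neg=row["p_ref_given_neg"],
                    p_focal_unknown=p_unknown,
                    focal_decision=str(row.get("focal_decision", "reference")),
                    n_subjects=None if n is None else int(n),
                )
            )
        except (InvalidInputError, ConfigurationError) as err:
            raise InvalidInputError(f"row {i} ({row.get('study_id')!r}): {err}") from err
    return out


def read_scenarios(path) -> list[BinaryScenario]:
    """Read scenarios from a comma-separated file with a header row."""
    return scenarios_from_frame(pd.read_csv(path))


def write_scenarios(scenarios: Sequence[BinaryScenario], path) -> None:
    scenarios_to_frame(scenarios).to_csv(path, index=False)
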