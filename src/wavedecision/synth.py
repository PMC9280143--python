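"""Synthetic-experiment generator and parameter-recovery studies.

The generator emulates the between-subjects designs of the source
experiments: one group of ``n_subjects`` answers under each known condition,
one under the unknown condition, and each group's response frequency is an
independent binomial draw.  The condition marginal p(C+) is a design constant
(the experimenter sets the win/lose or defect/cooperate base rate) and is
never sampled.

In noise-free mode the observed unknown-condition probability is set to the
model's own prediction at the rule's fitted phase, making the generative
assumption explicit: analysing a noise-free scenario returns
theta_expt == theta_fit to machine precision (the round-trip property the
test suite checks).

Seeding: a single integer seed drives a ``numpy.random.SeedSequence`` whose
spawned children give each replicate its own substream, so replicate r is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InvalidInputError
from .scenario import (
    BinaryScenario,
    PhaseFitRule,
    analyze,
    fitted_phase,
    known_condition_phases,
    predict_unknown,
    preset_rule,
)

__all__ = ["SyntheticConfig", "generate_scenario", "recovery_experiment", "RecoverySummary"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and sampling design for one synthetic experiment.

    Defaults reproduce a two-stage gambling design with conditionals
    0.69/0.57 at equal condition marginals and groups of 200 subjects —
    typical of the source experiments.
    """

    paradigm: str = "gambling"
    p_ref_given_pos: float = 0.69
    p_ref_given_neg: float = 0.57
    p_cond_pos: float = 0.5
    focal_decision: str = "reference"
    n_subjects: Optional[int] = 200
    seed: Optional[int] = None
    n_replicates: int = 500
    study_id: str = "synthetic"
    rule: Optional[PhaseFitRule] = None

    def __post_init__(self) -> None:
        if self.n_subjects is not None and self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path!r} must hold a mapping")
        rule = raw.pop("rule", None)
        if rule is not None:
            rule = PhaseFitRule(form=rule["form"], cells=tuple(rule["cells"]))
        try:
            return cls(**raw, rule=rule)
        except TypeError as err:
            raise ConfigurationError(f"bad config key: {err}") from err

    @property
    def effective_rule(self) -> PhaseFitRule:
        return self.rule if self.rule is not None else preset_rule(self.paradigm)


def _noise_free_scenario(config: SyntheticConfig) -> BinaryScenario:
    base = BinaryScenario(
        study_id=config.study_id,
        paradigm=config.paradigm,
        p_cond_pos=config.p_cond_pos,
        p_ref_given_pos=config.p_ref_given_pos,
        p_ref_given_neg=config.p_ref_given_neg,
        focal_decision=config.focal_decision,
        n_subjects=config.n_subjects,
    )
    theta_fit = fitted_phase(known_condition_phases(base), config.effective_rule)
    p_unknown = predict_unknown(base, theta_fit).value
    if not 0.0 <= p_unknown <= 1.0:
        raise InvalidInputError(
            f"configured truth predicts an unknown-condition probability of {p_unknown:.4f}, "
            "outside [0, 1]; no binomial response frequency can realise it"
        )
    return replace(base, p_focal_unknown=p_unknown)


def generate_scenario(
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> BinaryScenario:
    """Build one scenario from ground-truth phases, optionally with noise.

    Noise-free (``n_subjects=None``): the unknown-condition probability is
    the model's own prediction at the rule's fitted phase.  Noisy: the two
    conditional response probabilities and the unknown-condition probability
    are each replaced by a binomial sample frequency over ``n_subjects``
    independent subjects.
    """
    truth = _noise_free_scenario(config)
    if config.n_subjects is None:
        return truth
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    return replace(
        truth,
        p_ref_given_pos=rng.binomial(n, truth.p_ref_given_pos) / n,
        p_ref_given_neg=rng.binomial(n, truth.p_ref_given_neg) / n,
        p_focal_unknown=rng.binomial(n, truth.p_focal_unknown) / n,
    )


@dataclass(frozen=True)
class RecoverySummary:
    """Bias and spread of recovered phases over replicated noisy experiments."""

    config: SyntheticConfig
    truth: dict[str, float]
    replicates: pd.DataFrame
    n_failed: int

    @property
    def bias(self) -> dict[str, float]:
        return {
            k: float(self.replicates[k].mean() - v) for k, v in self.truth.items()
        }

    @property
    def sd(self) -> dict[str, float]:
        return {k: float(self.replicates[k].std(ddof=1)) for k in self.truth}

    @property
    def clamped_fraction(self) -> float:
        """Fraction of replicates where any inverted cosine hit the boundary."""
        return float(self.replicates["any_clamped"].mean())

    def to_dict(self) -> dict:
        return {
            "n_replicates": len(self.replicates),
            "n_failed": self.n_failed,
            "truth": self.truth,
            "bias": self.bias,
            "sd": self.sd,
            "clamped_fraction": self.clamped_fraction,
        }


def recovery_experiment(config: SyntheticConfig) -> RecoverySummary:
    """Measure phase recovery under binomial response noise.

    Runs ``config.n_replicates`` independent noisy experiments at the
    configured ground truth, analyses each, and summarises bias and SD of the
    recovered experimental phase and of each cell phase against the
    noise-free truth.  Replicates whose sampled frequencies leave a phase
    undefined (a degenerate marginal) are counted in ``n_failed`` rather than
    silently dropped.
    """
    if config.n_subjects is None:
        raise ConfigurationError("recovery_experiment requires noisy mode (n_subjects set)")
    truth_scenario = _noise_free_scenario(config)
    truth_result = analyze(truth_scenario, rule=config.effective_rule)
    truth = {
        "theta_expt": truth_result.theta_expt.theta_deg,
        **{f"theta{i}": truth_result.cell_table.theta(i) for i in range(1, 5)},
    }
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            scenario = generate_scenario(config, rng=rng)
            result = analyze(scenario, rule=config.effective_rule)
        except Exception:
            n_failed += 1
            continue
        rows.append(
            {
                "theta_expt": result.theta_expt.theta_deg,
                **{f"theta{i}": result.cell_table.theta(i) for i in range(1, 5)},
                "any_clamped": result.theta_expt.clamped or result.cell_table.any_clamped,
            }
        )
    if not rows:
        raise InvalidInputError("every replicate failed; check the configuration")
    return RecoverySummary(
        config=config,
        truth=truth,
        replicates=pd.DataFrame(rows),
        n_failed=n_failed,
    )
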