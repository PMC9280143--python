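"""Interference phases from event-related potential (ERP) amplitude triplets.

Each electrode contributes mean ERP amplitudes (in microvolts) for a
positive-, a negative- and a neutral-valence stimulus class.  Treating wave
intensity as amplitude squared (the proportionality constant cancels), the
neutral response is modelled as the interference of the positive and
negative responses:

    I_neutral = I_pos + I_neg + 2*sqrt(I_pos*I_neg)*cos(theta)

so the electrode's interference phase is recovered with the same inversion
used for behavioral probabilities.  The phase is scale-invariant: multiplying
all three amplitudes by any k > 0 leaves theta unchanged, which is why phases
are comparable across electrodes while raw amplitudes are not.

Amplitude signs: component amplitudes (N270, P300) are treated as magnitudes
as reported; no polarity handling is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import PhaseResult, invert_phase
from .exceptions import DegenerateInputError, InsufficientDataError, InvalidInputError
from .stability import StabilitySummary, summarize_phases

__all__ = [
    "ErpTriplet",
    "ErpStabilityReport",
    "erp_phase",
    "erp_stability_report",
    "read_electrode_table",
]

AMPLITUDE_COLUMNS = ("amplitude_pos", "amplitude_neg", "amplitude_neutral")


@dataclass(frozen=True)
class ErpTriplet:
    """One electrode's positive/negative/neutral mean amplitudes (microvolts)."""

    electrode: str
    amplitude_pos: float
    amplitude_neg: float
    amplitude_neutral: float

    def __post_init__(self) -> None:
        for name in AMPLITUDE_COLUMNS:
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(
                    f"{self.electrode}: {name} must be a non-negative magnitude, got {v!r}"
                )
            object.__setattr__(self, name, v)

    @property
    def intensities(self) -> tuple[float, float, float]:
        """(I_pos, I_neg, I_neutral) with intensity = amplitude squared."""
        return (
            self.amplitude_pos**2,
            self.amplitude_neg**2,
            self.amplitude_neutral**2,
        )


def erp_phase(triplet: ErpTriplet) -> PhaseResult:
    """Interference phase of one electrode's amplitude triplet.

    Raises
    ------
    DegenerateInputError
        If the positive or negative amplitude is zero.
    """
    i_pos, i_neg, i_neutral = triplet.intensities
    try:
        return invert_phase(i_neutral, i_pos, i_neg)
    except DegenerateInputError as err:
        raise DegenerateInputError(f"electrode {triplet.electrode}: {err}") from err


@dataclass(frozen=True)
class ErpStabilityReport:
    """Phase-vs-amplitude stability across electrodes.

    ``phase_more_stable`` is true when the CV of the derived phases is below
    the smallest CV of the three amplitude columns — the signature that the
    interference phase, not the raw amplitude, is the conserved quantity.
    """

    phases: StabilitySummary
    amplitudes: dict[str, StabilitySummary]
    phase_results: tuple[PhaseResult, ...]
    electrodes: tuple[str, ...]

    @property
    def phase_more_stable(self) -> bool:
        return self.phases.cv < min(s.cv for s in self.amplitudes.values())


def erp_stability_report(triplets: Sequence[ErpTriplet]) -> ErpStabilityReport:
    """Compare phase stability with amplitude stability across electrodes.

    Raises
    ------
    InsufficientDataError
        For fewer than two electrodes.
    """
    if len(triplets) < 2:
        raise InsufficientDataError(
            f"need at least 2 electrodes to assess stability, got {len(triplets)}"
        )
    phase_results = tuple(erp_phase(t) for t in triplets)
    phases = summarize_phases([p.theta_deg for p in phase_results])
    amplitudes = {
        col: summarize_phases([getattr(t, col) for t in triplets])
        for col in AMPLITUDE_COLUMNS
    }
    return ErpStabilityReport(
        phases=phases,
        amplitudes=amplitudes,
        phase_results=phase_results,
        electrodes=tuple(t.electrode for t in triplets),
    )


def read_electrode_table(path) -> list[ErpTriplet]:
    """Read electrode triplets from a comma-separated file.

    Required columns: ``electrode, amplitude_pos, amplitude_neg,
    amplitude_neutral``; extra columns (component name, study id, printed
    reference values) are ignored.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("electrode", *AMPLITUDE_COLUMNS) if c not in df.columns]
    if missing:
        raise InvalidInputError(f"electrode table is missing columns: {missing}")
    return [
        ErpTriplet(
            electrode=str(row["electrode"]),
            amplitude_pos=row["amplitude_pos"],
            amplitude_neg=row["amplitude_neg"],
            amplitude_neutral=row["amplitude_neutral"],
        )
        for _, row in df.iterrows()
    ]
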