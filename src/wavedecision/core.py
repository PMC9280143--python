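"""Closed-form wave-interference mathematics.

Two waves of equal frequency with intensities ``I1, I2`` and phase offset
``theta`` superpose to a resultant of intensity

    I = I1 + I2 + 2*sqrt(I1*I2)*cos(theta)

and, because detection probability is proportional to intensity, the same
algebra combines two probability-weighted decision paths into the probability
of the decision when the condition is unknown.  Inverting the formula
recovers the interference phase from three observed quantities; a cosine
that lands outside [-1, 1] (possible because the combined value is not a
normalised probability law) is clamped to the boundary and flagged, which is
what produces 180.00-degree cells in phase tables.

Phases are degrees at every public boundary; radians appear only inside the
trigonometric calls.  Reported phase differences live on the arccos principal
branch [0, 180]; the pairwise differences feeding a cosine are signed, but
cosine is even so the branch choice is observationally irrelevant.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "WaveComponent",
    "PhaseResult",
    "CombinedProbability",
    "resultant_intensity",
    "two_wave_probability",
    "invert_phase",
]


@dataclass(frozen=True)
class WaveComponent:
    """One interfering wave: an intensity (or probability) and a phase.

    Parameters
    ----------
    intensity
        Non-negative intensity; for behavioral data this is a probability,
        for electrophysiological data a squared amplitude.  Unitless.
    phase_deg
        Wave phase in degrees, reduced to [0, 360).
    """

    intensity: float
    phase_deg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise InvalidInputError(
                f"intensity must be finite and >= 0, got {self.intensity!r}"
            )
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)

    @property
    def amplitude(self) -> float:
        """Non-negative square root of the intensity."""
        return math.sqrt(self.intensity)

    @property
    def phasor(self) -> complex:
        """Complex representation ``amplitude * exp(i*phase)``."""
        return cmath.rect(self.amplitude, math.radians(self.phase_deg))


@dataclass(frozen=True)
class PhaseResult:
    """An inverted interference phase.

    ``theta_deg`` is ``arccos`` of the cosine after clamping to [-1, 1] and
    therefore lies in [0, 180].  ``raw_cosine`` keeps the pre-clamp value so
    reports can mark boundary cells; ``clamped`` is true iff |raw_cosine| > 1.
    """

    theta_deg: float
    raw_cosine: float
    clamped: bool

    @classmethod
    def from_cosine(cls, raw_cosine: float) -> "PhaseResult":
        clamped = abs(raw_cosine) > 1.0
        cos = min(1.0, max(-1.0, raw_cosine))
        return cls(theta_deg=math.degrees(math.acos(cos)), raw_cosine=raw_cosine, clamped=clamped)


@dataclass(frozen=True)
class CombinedProbability:
    """Raw two-path combined probability plus an out-of-range indicator.

    The interference combination is not a normalised probability law: the
    raw value may leave [0, 1] and is deliberately not truncated.
    """

    value: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.value


def _check_nonnegative(name: str, x: float) -> float:
    x = float(x)
    if not math.isfinite(x) or x < 0:
        raise InvalidInputError(f"{name} must be finite and >= 0, got {x!r}")
    return x


def resultant_intensity(components: Iterable[WaveComponent | Sequence[float]]) -> float:
    """Intensity of the superposition of ``components``.

    Accepts :class:`WaveComponent` instances or ``(intensity, phase_deg)``
    pairs.  Returns

        sum_i I_i  +  sum_{j>i} 2*sqrt(I_j*I_i)*cos(theta_j - theta_i)

    which equals the squared modulus of the phasor sum
    ``sum_i sqrt(I_i)*exp(i*theta_i)``.
    """
    comps = [
        c if isinstance(c, WaveComponent) else WaveComponent(*c) for c in components
    ]
    if not comps:
        raise InvalidInputError("at least one wave component is required")
    total = sum(c.intensity for c in comps)
    for j in range(1, len(comps)):
        for i in range(j):
            cj, ci = comps[j], comps[i]
            total += (
                2.0
                * cj.amplitude
                * ci.amplitude
                * math.cos(math.radians(cj.phase_deg - ci.phase_deg))
            )
    # guard against tiny negative round-off in fully destructive cases
    return max(total, 0.0) if total > -1e-12 else total


def two_wave_probability(p1: float, p2: float, theta_deg: float) -> CombinedProbability:
    """Combine two probability-weighted paths at interference phase ``theta_deg``.

    Returns ``p1 + p2 + 2*sqrt(p1*p2)*cos(theta)`` as a
    :class:`CombinedProbability`.  At ``theta = 90`` the interference term
    vanishes and the classical law of total probability is recovered.  The
    value is attainable within ``[(sqrt(p1)-sqrt(p2))**2, (sqrt(p1)+sqrt(p2))**2]``
    and may exceed [0, 1]; it is returned raw with ``out_of_range`` set.
    """
    p1 = _check_nonnegative("p1", p1)
    p2 = _check_nonnegative("p2", p2)
    value = p1 + p2 + 2.0 * math.sqrt(p1 * p2) * math.cos(math.radians(theta_deg))
    return CombinedProbability(value=value, out_of_range=not (0.0 <= value <= 1.0))


def invert_phase(p_combined: float, p1: float, p2: float) -> PhaseResult:
    """Recover the interference phase from a combined value and its two paths.

    Solves ``p_combined = p1 + p2 + 2*sqrt(p1*p2)*cos(theta)`` for ``theta``:

        cos(theta) = (p_combined - p1 - p2) / (2*sqrt(p1*p2))

    Cosines outside [-1, 1] are clamped (flagged), never rejected: observed
    probability triples routinely produce them because the combination is not
    a normalised law.  Round-trips :func:`two_wave_probability` whenever the
    result is unclamped.

    Raises
    ------
    DegenerateInputError
        If ``p1`` or ``p2`` is zero: an absent path carries no phase.
    """
    p1 = _check_nonnegative("p1", p1)
    p2 = _check_nonnegative("p2", p2)
    if p1 == 0.0 or p2 == 0.0:
        raise DegenerateInputError(
            "phase is undefined when either interfering component vanishes "
            f"(p1={p1!r}, p2={p2!r})"
        )
    raw = (float(p_combined) - p1 - p2) / (2.0 * math.sqrt(p1 * p2))
    return PhaseResult.from_cosine(raw)
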