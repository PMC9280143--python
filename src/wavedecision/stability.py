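"""Summary statistics for phase- and probability-stability analyses.

Conventions (chosen so the statistics agree with how phase tables are
conventionally summarised):

* mean +/- SD uses the *sample* standard deviation (n-1 denominator), and the
  coefficient of variation (CV) is sample SD over mean;
* RMSD between paired phase sequences uses the *population* denominator N;
* MAPE divides by the *fitted* value by default (``denominator="observed"``
  is available; MAPE is not symmetric in its arguments).

Exclusion of individual studies from a summary is explicit configuration
(an ``exclude`` argument), never inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "StabilitySummary",
    "summarize_phases",
    "rmsd",
    "mape",
    "uniform_window_probability",
]


@dataclass(frozen=True)
class StabilitySummary:
    """Mean, sample SD and CV of a collection, with optional paired stats."""

    n: int
    mean: float
    sample_sd: float
    cv: Optional[float] = None
    rmsd: Optional[float] = None
    mape: Optional[float] = None
    exclusions: tuple[str, ...] = ()

    def __str__(self) -> str:  # "134.87 ± 5.10" style
        s = f"{self.mean:.2f} ± {self.sample_sd:.2f} (n={self.n}"
        if self.cv is not None:
            s += f", CV={self.cv:.2f}"
        if self.rmsd is not None:
            s += f", RMSD={self.rmsd:.2f}"
        if self.mape is not None:
            s += f", MAPE={self.mape:.2f}"
        return s + ")"


def summarize_phases(
    values: Sequence[float],
    exclusions: Sequence[str] = (),
) -> StabilitySummary:
    """Mean and sample SD (and CV when the mean is nonzero) of ``values``.

    Raises
    ------
    InsufficientDataError
        For fewer than two values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = sd / mean if mean != 0.0 else None
    return StabilitySummary(
        n=int(arr.size), mean=mean, sample_sd=sd, cv=cv, exclusions=tuple(exclusions)
    )


def rmsd(a: Sequence[float], b: Sequence[float]) -> float:
    """Root-mean-square deviation between paired sequences (denominator N)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise InvalidInputError(
            f"rmsd needs equal-length non-empty sequences, got {a.size} and {b.size}"
        )
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mape(
    observed: Sequence[float],
    fitted: Sequence[float],
    denominator: str = "fitted",
) -> float:
    """Mean absolute percentage error between observed and fitted values.

    ``denominator="fitted"`` (default) averages |obs - fit| / fit;
    ``"observed"`` averages |obs - fit| / obs.  The two conventions differ
    and the statistic is not symmetric in its arguments.
    """
    obs = np.asarray(list(observed), dtype=float)
    fit = np.asarray(list(fitted), dtype=float)
    if obs.shape != fit.shape or obs.size == 0:
        raise InvalidInputError(
            f"mape needs equal-length non-empty sequences, got {obs.size} and {fit.size}"
        )
    if denominator == "fitted":
        den = fit
    elif denominator == "observed":
        den = obs
    else:
        raise InvalidInputError(f"denominator must be 'fitted' or 'observed', got {denominator!r}")
    if np.any(den == 0):
        raise InvalidInputError("mape denominator contains zeros")
    return float(np.mean(np.abs(obs - fit) / den))


def uniform_window_probability(
    n: int,
    width: float,
    domain: float = 180.0,
    method: str = "range_exact",
) -> float:
    """Probability that ``n`` i.i.d. uniforms on [0, domain] cluster in a window.

    ``method="range_exact"`` is the exact probability that the sample range
    is at most ``width``:

        P(range <= w) = n*(w/L)**(n-1) - (n-1)*(w/L)**n

    ``method="naive_power"`` is the cruder bound ``(w/L)**n`` (the chance all
    n points land in one *fixed* window), always <= the exact value.
    """
    if n < 2:
        raise InvalidInputError(f"n must be >= 2, got {n}")
    if not 0 < width <= domain:
        raise InvalidInputError(f"need 0 < width <= domain, got width={width}, domain={domain}")
    r = width / domain
    if method == "range_exact":
        return n * r ** (n - 1) - (n - 1) * r**n
    if method == "naive_power":
        return r**n
    raise InvalidInputError(f"method must be 'range_exact' or 'naive_power', got {method!r}")
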