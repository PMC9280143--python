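"""Exception hierarchy for wavedecision."""


class WaveDecisionError(Exception):
    """Base class for all wavedecision errors."""


class InvalidInputError(WaveDecisionError, ValueError):
    """An input violates a precondition (negative intensity, probability outside [0, 1], ...)."""


class DegenerateInputError(WaveDecisionError, ValueError):
    """A quantity needed for phase inversion vanishes, leaving the phase undefined."""


class InsufficientDataError(WaveDecisionError, ValueError):
    """Too few observations for the requested summary statistic."""


class MissingObservationError(WaveDecisionError, ValueError):
    """An operation requires an observed unknown-condition probability that is absent."""


class ConfigurationError(WaveDecisionError, ValueError):
    """Unknown preset, malformed rule, or invalid simulation configuration."""
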