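"""Exception hierarchy for the rhythmxmit package."""


class RhythmxmitError(Exception):
    """Base class for all package errors."""


class FormatError(RhythmxmitError):
    """Malformed input file (bad header, unknown channel name, ...)."""


class SamplingError(RhythmxmitError):
    """Non-uniform or inconsistent time base."""


class EmptyInputError(RhythmxmitError):
    """Empty file or empty record collection where content is required."""


class ParameterError(RhythmxmitError):
    """Invalid analysis parameter (e.g. integration window below 2 samples)."""


class LengthError(RhythmxmitError):
    """Trace too short for the requested operation."""


class InsufficientEventsError(RhythmxmitError):
    """Fewer events than the metric requires (e.g. < 2 bursts for f_inst)."""


class NormalizationError(RhythmxmitError):
    """Zero or negative normalization constant."""


class WindowRangeError(RhythmxmitError):
    """Analysis window falls outside the recording."""


class AlignmentError(RhythmxmitError):
    """Mismatched time bases between simultaneously recorded signals."""


class ConfigError(RhythmxmitError):
    """Infeasible or inconsistent configuration."""


class DegenerateDataError(RhythmxmitError):
    """Data degenerate for the requested statistic (e.g. zero-variance pairs)."""


class MissingChannelError(RhythmxmitError):
    """A required recording site is absent from the input."""
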