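"""Exception hierarchy shared by all pipeline stages.

``InputError`` maps to CLI exit code 2, ``AnalysisError`` to exit code 3.
"""


class RetinodexError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class InputError(RetinodexError):
    """Malformed or inconsistent input (shapes, units, labels, files)."""

    exit_code = 2


class ConfigurationError(InputError):
    """A phantom or pipeline configuration violates its invariants."""


class AnalysisError(RetinodexError):
    """The data were readable but an analysis stage could not proceed
    (empty segmentation, missing waveform landmark, ...)."""

    exit_code = 3
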