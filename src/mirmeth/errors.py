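"""Typed exceptions raised by the pipeline.

Every malformed input raises one of these; nothing fails silently.
"""


class MirmethError(Exception):
    """Base class for all pipeline errors."""


class InputFormatError(MirmethError):
    """A file is structurally unreadable (missing columns, bad dialect)."""


class ValidationError(MirmethError):
    """A file parsed but violates a data invariant (duplicates, bad enums)."""


class ConfigError(MirmethError):
    """The run configuration is inconsistent or incomplete."""


class AnalysisError(MirmethError):
    """A statistical operation's preconditions are not met."""
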