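"""Exception hierarchy for fibroscore.

Every error raised on purpose by the package derives from
:class:`FibroscoreError`, so callers can catch one type at the pipeline
boundary while tests can assert on the specific subclass.
"""


class FibroscoreError(Exception):
    """Base class for all fibroscore errors."""


class ConfigError(FibroscoreError):
    """Invalid simulation or pipeline configuration; message names the field."""


class DegenerateInputError(FibroscoreError):
    """Input too small or without variance for the requested statistic."""


class PairingError(FibroscoreError):
    """Paired samples whose lengths or donor alignments do not match."""


class MissingDataError(FibroscoreError):
    """Incomplete blocks in a repeated-measures layout; message lists donors."""


class DomainError(FibroscoreError):
    """Operation called outside its domain (e.g. Friedman with k < 3)."""


class EmptySelectionError(FibroscoreError):
    """A table slice (condition, material, readout) selected no rows."""


class SizeError(FibroscoreError):
    """Combinatorial guard tripped (exact enumeration requested for n > 20)."""


class SchemaError(FibroscoreError):
    """Readout-table file whose header or dtypes do not match the schema."""


class ParseError(FibroscoreError):
    """Malformed rows in an input file; message carries line numbers."""


class InternalConsistencyError(FibroscoreError):
    """A computed object violated one of its own invariants (never silent)."""


class InsufficientOverlapError(FibroscoreError):
    """Fewer than two materials shared between ranking and reference."""
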