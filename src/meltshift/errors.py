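"""Exception hierarchy shared across the package.

All meltshift errors derive from :class:`MeltshiftError`, so callers (and
the command-line layer, which maps them to exit status 1) can catch one
type.
"""


class MeltshiftError(Exception):
    """Base class for all errors raised by meltshift."""


class FormatError(MeltshiftError):
    """A file does not conform to the documented tabular dialect."""


class ValidationError(MeltshiftError):
    """Input values violate a documented invariant (e.g. negative intensity)."""


class NormalizationError(MeltshiftError):
    """A profile cannot be scaled to its reference temperature."""


class ConfigError(MeltshiftError):
    """A simulation or run configuration is infeasible or invalid."""


class DegenerateDesignError(MeltshiftError):
    """A factorial table has too few replicates or zero variance everywhere."""
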