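"""Exception hierarchy shared across the package."""


class PTMDriverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PTMDriverError):
    """An invalid configuration value; the message names the offending field."""


class ConsistencyError(PTMDriverError):
    """Cross-references between inputs do not line up (e.g. unknown protein id)."""


class FormatError(PTMDriverError):
    """A malformed input file; the message names the file and, where known, the line."""


class DegenerateInputError(PTMDriverError):
    """An analysis was asked to run on an input that cannot support it
    (e.g. a survival stratum with a single group)."""
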