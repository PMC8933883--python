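"""Exception hierarchy."""


class PlastokitError(Exception):
    """Base class for all package errors."""


class FormatError(PlastokitError):
    """Malformed or empty input file."""


class AlphabetError(PlastokitError):
    """Sequence is not nucleotide."""


class ConsistencyError(PlastokitError):
    """Inputs that must describe the same genome do not."""


class ConfigError(PlastokitError):
    """Invalid synthetic-genome configuration or edit."""


class StructureNotFoundError(PlastokitError):
    """No quadripartite structure (inverted-repeat pair) detected."""


class AmbiguousStructureError(PlastokitError):
    """Single-copy arcs of equal length; LSC/SSC assignment is ambiguous."""

    def __init__(self, msg, assignments=None):
        super().__init__(msg)
        self.assignments = assignments or []


class SaturationError(PlastokitError):
    """Distance correction out of the log domain."""


class NoSitesError(PlastokitError):
    """No alignment columns survive gap/N deletion."""
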