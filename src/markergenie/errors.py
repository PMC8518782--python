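"""Exception hierarchy shared across the package."""


class MarkerGenieError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MarkerGenieError):
    """A file does not look like the expected format at all."""


class HmmParseError(MarkerGenieError):
    """A file is recognisably HMMER3 but malformed inside a record."""


class ValidationError(MarkerGenieError):
    """An in-memory object violates its invariants or preconditions."""


class ConstructionError(MarkerGenieError):
    """A model cannot be built from the given inputs."""


class ConfigurationError(MarkerGenieError):
    """Registry/config inconsistency (e.g. a target HMM without cutoffs)."""
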