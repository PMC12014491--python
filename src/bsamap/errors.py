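"""Exception hierarchy shared across the pipeline."""


class BsamapError(Exception):
    """Base class for all package errors."""


class FormatError(BsamapError):
    """A file does not conform to its declared format."""


class ConfigError(BsamapError):
    """Invalid or inconsistent configuration."""


class ValidationError(BsamapError):
    """A domain object violates its invariants."""


class ConsistencyError(BsamapError):
    """Inputs that must agree (e.g. genome vs. VCF ref alleles) do not."""


class DataError(BsamapError):
    """A table or series is missing required observations."""


class SizingError(BsamapError):
    """A simulation request does not fit the sequence space available."""


class PlacementError(BsamapError):
    """No eligible site exists for a requested simulated feature."""
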