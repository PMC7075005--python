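"""Exception hierarchy shared across the pipeline stages."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HerbnetError):
    """A tabular or graph file does not match the expected schema."""


class InvalidCompoundError(HerbnetError):
    """A compound record carries a missing or out-of-range descriptor."""

    def __init__(self, message: str, compound_ids=()):
        super().__init__(message)
        self.compound_ids = tuple(compound_ids)


class ConfigError(HerbnetError):
    """A pipeline or stage configuration is inconsistent or incomplete."""


class GenerationError(HerbnetError):
    """A synthetic-data specification could not be satisfied."""
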