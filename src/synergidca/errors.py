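"""Exception types shared across the package."""


class SynergidCaError(Exception):
    """Base class for all package-specific errors."""


class UnknownPresetError(SynergidCaError, KeyError):
    """Raised when a genotype preset name is not recognised."""


class ConfigError(SynergidCaError, ValueError):
    """Raised when a configuration object violates its invariants."""


class FormatError(SynergidCaError, ValueError):
    """Raised when an on-disk stack, ROI or trace file is malformed."""


class ContractError(SynergidCaError, ValueError):
    """Raised when an operation is called outside its precondition."""
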