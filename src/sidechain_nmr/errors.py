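"""Exception types shared across the package."""


class SideChainNMRError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(SideChainNMRError, ValueError):
    """A physical parameter is out of its admissible range or non-finite."""


class PropagationError(SideChainNMRError, ArithmeticError):
    """Numerical failure while evolving magnetization (singular/overflow)."""


class MappingError(SideChainNMRError, KeyError):
    """Profile/model or atom/basis labels cannot be matched."""


class ConfigurationError(SideChainNMRError, ValueError):
    """A fit or analysis configuration is inconsistent (e.g. dof <= 0)."""


class DomainError(SideChainNMRError, ValueError):
    """An argument lies outside the mathematical domain of an expression."""


class UnmeasurableError(SideChainNMRError, ValueError):
    """The requested quantity cannot be extracted from the data (e.g. the
    reference peak does not rise above the spectral noise)."""
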