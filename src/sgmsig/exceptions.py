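"""Exception types shared across the package."""


class SgmsigError(Exception):
    """Base class for package errors."""


class InputError(SgmsigError, ValueError):
    """An argument violates an operation's preconditions."""


class DomainError(SgmsigError, ValueError):
    """An argument is outside the operation's domain (e.g. a stop codon)."""


class FormatError(SgmsigError, ValueError):
    """An input file violates its format contract."""


class DataIntegrityError(SgmsigError, ValueError):
    """Input data contradicts the reference it should match."""


class DegenerateResultError(SgmsigError, ValueError):
    """The requested quantity is undefined for this input (e.g. zero mass)."""


class ConfigError(SgmsigError, ValueError):
    """An unrecognised or inconsistent configuration value."""
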