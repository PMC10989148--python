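"""Exception hierarchy used across the package."""


class CoexpanelError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CoexpanelError, ValueError):
    """Input data violates a declared invariant (e.g. negative FPKM)."""


class ParseError(CoexpanelError, ValueError):
    """A delimited input file could not be interpreted."""


class ConfigurationError(CoexpanelError, ValueError):
    """Inconsistent run configuration (missing condition, shape mismatch...)."""


class ParameterError(CoexpanelError, ValueError):
    """A numeric parameter is outside its admissible range."""


class StatisticsError(CoexpanelError, ValueError):
    """A statistical routine cannot run (too few replicates, one cluster...)."""
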