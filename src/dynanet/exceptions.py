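"""Exception hierarchy shared across the package."""


class DynanetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DynanetError, ValueError):
    """A required column is missing or a cell cannot be parsed."""


class DataIntegrityError(DynanetError, ValueError):
    """Duplicate keys or registry violations inside a dataset."""


class PanelLookupError(DynanetError, KeyError):
    """Unknown subgroup, mediator, or interval."""


class ConfigError(DynanetError, ValueError):
    """Invalid analysis configuration (thresholds, MCMC settings, ...)."""


class InfeasibleStructureError(DynanetError, ValueError):
    """A planted correlation structure admits no valid covariance."""
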