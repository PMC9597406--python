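"""Exception hierarchy.

``ConfigurationError`` covers invalid parameters supplied by the caller
(bad filter band, unknown condition label); ``DataError`` covers inputs
that are structurally valid but unusable (too few strides, NaNs in a
channel, a zero baseline).
"""


class GaitCostsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitCostsError):
    """A parameter or configuration value is invalid."""


class DataError(GaitCostsError):
    """Input data cannot be analysed as requested."""


class InsufficientStridesError(DataError):
    """Fewer complete strides than the analysis requires."""


class IncompleteActivationError(DataError):
    """An activation table is missing one or more muscle channels."""


class DegenerateBaselineError(DataError):
    """A baseline activation mean is zero; normalization is undefined."""
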