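"""Exception hierarchy.

All package errors derive from :class:`PortalQAError` so callers can catch one
type at the CLI boundary; most also derive from the matching builtin
(``ValueError`` / ``KeyError``) so library users get conventional semantics.
"""


class PortalQAError(Exception):
    """Base class for all portalqa errors."""


class ConfigError(PortalQAError, KeyError):
    """Missing or malformed configuration; message names the offending key."""


class DomainError(PortalQAError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class UndefinedSpectrumError(DomainError):
    """Spectrum with zero total weight where a fraction is requested."""


class GeometryError(PortalQAError, ValueError):
    """Imaging geometry inconsistent with the phantom or canvas."""


class LayoutError(PortalQAError, ValueError):
    """A required phantom element ROI cannot be placed on the image."""


class InsufficientSamplingError(PortalQAError, ValueError):
    """ROI covers fewer bar periods than the analysis requires."""


class ProfileFormatError(PortalQAError, ValueError):
    """Malformed dose-profile file; message names the line/field."""


class ContractError(PortalQAError, ValueError):
    """Two inputs that must agree (e.g. normalization modes) do not."""
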