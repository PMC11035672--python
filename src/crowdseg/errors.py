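"""Exception hierarchy shared across the package."""


class CrowdsegError(Exception):
    """Base class for all package-specific errors."""


class ComparabilityError(CrowdsegError):
    """Two masks with different dimensions were compared."""


class MaskFormatError(CrowdsegError):
    """A raster file is not a readable single-channel binary mask."""


class ManifestSchemaError(CrowdsegError):
    """A manifest table violates its schema (columns, uniqueness, roles)."""


class ConfigurationError(CrowdsegError):
    """A campaign parameter or reference-lookup setting is invalid."""


class ProtocolError(CrowdsegError):
    """The annotation protocol was violated (e.g. scoring before training)."""


class DomainError(CrowdsegError, ValueError):
    """An operation received a value outside its mathematical domain."""
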