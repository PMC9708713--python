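"""Exception types shared across the package."""


class PetDeblurError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PetDeblurError):
    """A configuration value violates a documented constraint."""


class FormatError(PetDeblurError):
    """An input file does not conform to the expected on-disk format."""


class PlacementError(PetDeblurError):
    """A lesion sphere could not be realized at the requested location."""


class GridMismatchError(PetDeblurError):
    """Two volumes that must share a grid do not."""
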