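"""Exception hierarchy shared across the package."""


class CampimetryError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CampimetryError, ValueError):
    """Malformed or out-of-contract input data."""


class DomainError(CampimetryError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateScaleError(CampimetryError, ValueError):
    """A luminance scale unusable for the requested computation
    (e.g. non-positive fitted luminance in a chi-square statistic)."""


class InvalidConfigError(CampimetryError, ValueError):
    """An exam configuration that cannot produce a valid test."""


class StateError(CampimetryError, RuntimeError):
    """Operation applied to an object in the wrong lifecycle state."""


class IncompatibleResultsError(CampimetryError, ValueError):
    """Two results that cannot be compared (different grid/vector/scale)."""


class StorageError(CampimetryError, ValueError):
    """Malformed registry line, settings file or result folder."""
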