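"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`KneemorphError`, so callers (and the CLI) can catch one type.
"""


class KneemorphError(Exception):
    """Base class for all kneemorph errors."""


# --- geometry ---------------------------------------------------------------

class DegenerateGeometryError(KneemorphError):
    """Coincident or otherwise degenerate points make a construction undefined."""


class UndefinedBisectorError(DegenerateGeometryError):
    """The two rays are exactly opposite; the internal bisector is undefined."""


class EmptyContourError(KneemorphError):
    """A contour with no points was supplied where at least one is required."""


class NoTangentError(KneemorphError):
    """No supporting line from the apex exists (apex inside/on the convex hull)."""


class MissingLandmarkError(KneemorphError):
    """A landmark required for the requested angle is absent (strict mode)."""


class ConstructionError(KneemorphError):
    """Requested true angles cannot be realized by the synthetic limb template."""


# --- agreement --------------------------------------------------------------

class IncompleteDesignError(KneemorphError):
    """The crossed subjects x observers x occasions table has missing cells."""


class UndefinedIccError(KneemorphError):
    """Total variance is zero; the intraclass correlation is undefined."""


class LoamUndefinedError(KneemorphError):
    """Limits of agreement with the mean need at least two observers."""


class InsufficientReplicatesError(KneemorphError):
    """The repeatability coefficient needs at least two occasions."""


# --- io / config ------------------------------------------------------------

class SchemaError(KneemorphError):
    """A file does not match the documented column schema."""


class VocabularyError(SchemaError):
    """A landmark name outside the closed vocabulary (strict, no trimming)."""


class DuplicateRowError(SchemaError):
    """Duplicate (subject, observer, occasion, landmark) row."""


class ConfigError(KneemorphError):
    """Invalid or unknown run-configuration key/value."""
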