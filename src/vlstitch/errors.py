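"""Exception hierarchy shared across the toolkit.

All domain errors derive from :class:`VlsError` so callers (and the CLI)
can distinguish expected failure modes from programming errors.
"""


class VlsError(Exception):
    """Base class for all domain errors raised by vlstitch."""


class FormatError(VlsError):
    """A file could not be parsed as the expected image/layout format."""


class CalibrationError(VlsError):
    """Physical-scale metadata (microns per pixel) is missing or inconsistent."""


class LayoutError(VlsError):
    """A stitch layout is malformed or references unknown fragments."""


class MissingLabelError(VlsError):
    """A required annotation label (e.g. tumor_bed) is absent."""


class NotStageableError(VlsError):
    """Size-based ypT staging does not apply (chest-wall/skin involvement)."""


class DegenerateStatisticError(VlsError):
    """A reliability statistic is undefined for the given table
    (zero variance, or chance agreement equal to 1)."""
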