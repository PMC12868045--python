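"""Exception hierarchy for kinassess.

All package-specific failures derive from :class:`KinassessError` so callers
(and the CLI) can catch everything domain-related with one handler.
"""


class KinassessError(Exception):
    """Base class for all kinassess errors."""


class FormatError(KinassessError):
    """Malformed input file (bad header, missing column, unparseable cell)."""


class ValidationError(KinassessError):
    """Semantically invalid data or arguments (bad tag, non-monotonic time)."""


class ParameterError(KinassessError):
    """Out-of-range numeric parameter (cutoff above Nyquist, L <= 0, ...)."""


class LengthError(KinassessError):
    """Series too short for the requested operation."""


class DegenerateGeometryError(KinassessError):
    """Coincident joints or vanishing projection make a vector undefined."""


class DegenerateMovementError(KinassessError):
    """Movement too small for a smoothness measure (near-zero path length)."""


class UnrecoverableDropoutError(KinassessError):
    """A tracking gap is too long to interpolate."""


class SampleSizeError(KinassessError):
    """Too few observations for a statistical procedure."""
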