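"""Exception hierarchy.

All user-facing failures derive from :class:`SmsleakError` so the CLI can
map them to exit code 1; anything else is an internal error (exit 2).
"""


class SmsleakError(Exception):
    """Base class for all errors raised on invalid user input or data."""


class ConfigurationError(SmsleakError):
    """Acquisition parameters are inconsistent (e.g. nz not divisible by MB)."""


class GeometryError(SmsleakError):
    """A shift or grid quantity required to be integral is not."""


class CoordinateError(SmsleakError):
    """A voxel coordinate lies outside the acquisition grid."""


class ParameterError(SmsleakError):
    """An operation parameter is out of its valid range."""


class PlacementError(SmsleakError):
    """No feasible placement exists for a requested control region."""


class ComputationError(SmsleakError):
    """A statistic cannot be computed from the available data."""


class InputError(SmsleakError):
    """An input file is malformed or inconsistent with the configuration."""
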