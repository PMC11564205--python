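"""Exception hierarchy for tribomove."""


class TriboError(Exception):
    """Base class for all tribomove errors."""


class FormatError(TriboError):
    """A tabular input violates the documented schema."""


class ConfigError(TriboError):
    """A run configuration names an unknown field, key or value."""


class MissingScaleError(TriboError):
    """A physical-unit operation was requested without mm-per-pixel calibration."""


class DegenerateArenaError(TriboError):
    """Arena bounds collapse to a line or point; edge metrics are undefined."""


class DegeneratePathError(TriboError):
    """A track is too short or too degenerate for the requested path metric."""
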