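"""Exception hierarchy for fireflysim."""


class FireflySimError(Exception):
    """Base class for all fireflysim errors."""


class DomainError(FireflySimError, ValueError):
    """An argument is outside the physical/index domain of an operation."""


class CoverageError(FireflySimError, ValueError):
    """A high-resolution spectrum does not cover the requested band support."""


class CalibrationError(FireflySimError, RuntimeError):
    """A numerical calibration (anchor solve, scene depth solve) failed."""


class DegenerateFeatureError(FireflySimError, ValueError):
    """An absorption feature is degenerate (k >= 1 or non-positive peak)."""


class FormatError(FireflySimError, IOError):
    """A file on disk violates the expected on-disk format."""


class ConfigError(FireflySimError, ValueError):
    """A configuration mapping contains unknown or invalid keys."""
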