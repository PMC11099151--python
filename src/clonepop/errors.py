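"""Exception types shared across the package."""


class ClonepopError(Exception):
    """Base class for package errors."""


class ConfigurationError(ClonepopError):
    """Invalid model, scenario, or pipeline configuration."""


class BoundsError(ClonepopError):
    """A coordinate falls outside the simulated or annotated range."""


class ParseError(ClonepopError):
    """Malformed input file."""


class PlacementError(ClonepopError):
    """Random placement could not satisfy constraints after bounded retries."""
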