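"""Exception types shared across the package."""


class PulsechemError(Exception):
    """Base class for all package errors."""


class ValidationError(PulsechemError):
    """A species/reaction table or registry invariant failed."""


class InvalidParameterError(PulsechemError):
    """A physical parameter is outside its admissible range."""


class GeometryError(PulsechemError):
    """A position or direction violates the phantom geometry."""


class EnergyRangeError(PulsechemError):
    """An energy query fell outside the bundled table range."""


class ScoreError(PulsechemError):
    """A score is undefined (e.g. zero deposited energy)."""


class FitError(PulsechemError):
    """Nonlinear fit failed to converge from every start."""


class ConfigError(PulsechemError):
    """Malformed or incomplete run configuration."""
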