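"""Exception hierarchy for memcurv."""


class MemcurvError(Exception):
    """Base class for all memcurv errors."""


class ConstraintInfeasibleError(MemcurvError):
    """Requested geometry cannot satisfy the tether (edge-length) bounds."""


class DegenerateGeometryError(MemcurvError):
    """A face has (numerically) zero area, so its normal is undefined."""


class CorruptedStateError(MemcurvError):
    """The Monte Carlo state failed an internal consistency check."""


class InfeasibleConfigurationError(MemcurvError):
    """Requested particle placement is geometrically impossible."""


class OutOfSphereError(MemcurvError):
    """A tracked 2-D point lies outside the projected particle sphere."""


class UndefinedDirectionError(MemcurvError):
    """A zero vector has no direction on the sphere."""


class InsufficientDataError(MemcurvError):
    """Not enough samples to build the requested statistic."""


class OffsetUndefinedError(MemcurvError):
    """No far-field bins are populated, so the potential offset is undefined."""


class SingularFitError(MemcurvError):
    """Least-squares fit is singular (e.g. collinear points for a circle)."""


class ConfigError(MemcurvError):
    """Invalid or unparseable configuration file."""
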