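"""Exception hierarchy for spotcorr.

All domain errors derive from :class:`SpotcorrError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class SpotcorrError(Exception):
    """Base class for all spotcorr domain errors."""


class InvalidConfigError(SpotcorrError):
    """A configuration value is out of its legal range."""


class InvalidDistanceError(SpotcorrError):
    """A precomputed distance matrix violates symmetry/nonnegativity."""


class DegenerateGeneError(SpotcorrError):
    """A gene has zero variance within a scope; its correlation is undefined."""


class EmptyResultError(SpotcorrError):
    """Filtering or screening removed everything there was to test."""


class NotTestableError(SpotcorrError):
    """The requested test cannot be formed (e.g. <2 surviving regions)."""


class NotEstimableError(SpotcorrError):
    """An estimate cannot be formed (e.g. bootstrap neighborhood too small)."""


class SingularCovarianceError(SpotcorrError):
    """A covariance matrix is singular even after diagonal jitter."""


class SimulationConfigError(SpotcorrError):
    """Simulation inputs are inconsistent (shapes, non-PSD covariance, ...)."""
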