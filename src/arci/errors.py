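"""Exception hierarchy for AR identification, spectral analysis and resampling."""


class ArciError(Exception):
    """Base class for all package-specific errors."""


class IdentificationError(ArciError):
    """Least-squares AR identification failed (e.g. singular normal equations)."""


class DegenerateFitError(ArciError):
    """The fitted innovation variance is zero; downstream indexes are undefined."""


class UnstableModelError(ArciError):
    """The AR polynomial has roots on or outside the unit circle."""


class RepeatedPoleError(ArciError):
    """Two poles coincide within tolerance; the residue decomposition assumes simple poles."""


class ResamplingError(ArciError):
    """A resampling scheme could not produce the requested replicates."""


class SimulationError(ArciError):
    """A simulated trajectory diverged or could not be generated."""


class RRParseError(ArciError):
    """An R-R interval file could not be parsed."""
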