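"""Exception hierarchy for dpdsurf."""


class DpdsurfError(Exception):
    """Base class for all dpdsurf errors."""


class ParameterError(DpdsurfError, ValueError):
    """An invalid (non-physical) parameter value was supplied."""


class BeadLookupError(DpdsurfError, KeyError):
    """A bead type name is not part of the force field."""


class AngleLookupError(DpdsurfError, KeyError):
    """An angle triplet has no entry in the active force-field variant."""


class UnsupportedSpeciesError(DpdsurfError, ValueError):
    """A molecular species cannot be represented by the bead mapping."""


class CompositionError(DpdsurfError, ValueError):
    """A requested box composition is infeasible."""


class IntegrationError(DpdsurfError, RuntimeError):
    """The integrator produced non-finite coordinates or energies."""


class NotEquilibratedError(DpdsurfError, RuntimeError):
    """A time series is still drifting; the requested statistic is refused."""


class NotDemixedError(DpdsurfError, RuntimeError):
    """A biphasic trajectory shows no water/octanol phase separation."""
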