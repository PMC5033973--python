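"""Exception types shared across the package."""


class GlycontrolError(Exception):
    """Base class for all package errors."""


class ParameterError(GlycontrolError):
    """A kinetic constant is missing, non-positive, or inconsistent."""


class StateError(GlycontrolError):
    """A concentration state is invalid (missing species, negative value)."""


class ModelBuildError(GlycontrolError):
    """A model definition cannot be assembled from the given parameters."""


class IntegrationError(GlycontrolError):
    """Time integration diverged or produced non-finite values."""

    def __init__(self, message, last_state=None, t=None):
        super().__init__(message)
        self.last_state = last_state
        self.t = t


class SBMLError(GlycontrolError):
    """An SBML document could not be parsed or serialized."""
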