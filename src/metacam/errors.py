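"""Exception hierarchy for the toolkit."""


class MetaCamError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(MetaCamError, ValueError):
    """A caller-supplied parameter violates an operation's contract."""


class InputError(MetaCamError, ValueError):
    """Input data (shapes, values) violate an operation's contract."""


class CaptureError(MetaCamError):
    """Activations/gradients could not be captured from a model."""


class EnsembleError(MetaCamError):
    """An ensemble cannot be formed (e.g. no valid component maps)."""


class ScoringError(MetaCamError):
    """A saliency map cannot be scored (invalid map handed to ROAD)."""


class ConfigurationError(MetaCamError):
    """A configuration object is internally inconsistent."""


class FixtureError(MetaCamError):
    """A synthetic fixture failed to meet its own contract."""
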