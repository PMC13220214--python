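"""Exception hierarchy for campaign, retrieval and surrogate failures."""


class BoiclError(Exception):
    """Base class for all package-specific errors."""


class DuplicateObservationError(BoiclError):
    """A candidate id was observed (labeled) twice — a repeated experiment."""


class EmptyMemoryError(BoiclError):
    """An operation requiring labeled examples was called on empty memory."""


class UnknownCandidateError(BoiclError, KeyError):
    """A candidate id is not present in the pool or memory."""


class DimensionMismatchError(BoiclError, ValueError):
    """Embedding dimensions disagree between query and index."""


class ZeroVectorError(BoiclError, ValueError):
    """Cosine similarity is undefined for a zero-norm vector."""


class TemplateError(BoiclError, ValueError):
    """A prompt template is missing a required slot."""


class PredictionFailureError(BoiclError):
    """No completion for a candidate could be parsed into a number."""


class BackendError(BoiclError):
    """A completion backend could not serve a request."""


class ScoringError(BoiclError, ValueError):
    """An acquisition score is NaN or otherwise unusable."""


class PoolExhaustedError(BoiclError):
    """No unlabeled candidates remain to select from."""


class ObservationError(BoiclError, ValueError):
    """A reported label is non-finite or otherwise invalid."""


class CalibrationInputError(BoiclError, ValueError):
    """Calibration inputs are malformed (e.g. non-positive sigma)."""


class FittingError(BoiclError):
    """Uncertainty-scale fitting received degenerate inputs."""


class ConnectivityError(BoiclError):
    """The Isomap neighborhood graph is disconnected; increase n_neighbors."""


class CampaignError(BoiclError):
    """An optimization iteration could not be completed."""
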