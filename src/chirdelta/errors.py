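"""Exception hierarchy shared across the package."""


class ChirDeltaError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ChirDeltaError, ValueError):
    """A SMILES string could not be parsed into a molecule."""


class NoStereocenterError(ChirDeltaError, ValueError):
    """An operation requiring a tetrahedral stereocenter got an achiral input."""


class MultiCenterError(ChirDeltaError, ValueError):
    """An operation requiring a single stereocenter got a multi-center input."""


class MissingKeyError(ChirDeltaError, KeyError):
    """An embedding backend has no vector for the requested SMILES key."""

    def __init__(self, smiles: str, backend_id: str = ""):
        self.smiles = smiles
        self.backend_id = backend_id
        super().__init__(f"no vector for SMILES {smiles!r}"
                         + (f" in backend {backend_id!r}" if backend_id else ""))


class DimensionMismatchError(ChirDeltaError, ValueError):
    """A vector or matrix does not match the expected dimensionality."""


class TieError(ChirDeltaError, ValueError):
    """Retention times of an enantiomer pair are equal; elution order undefined."""


class MissingDataError(ChirDeltaError, ValueError):
    """A required value (retention time, experiment id, label) is absent."""


class MissingPredictionError(ChirDeltaError, KeyError):
    """A pair member has no prediction in the supplied prediction table."""


class EmptyTrainingSetError(ChirDeltaError, ValueError):
    """Nearest-neighbor search was asked to scan an empty training matrix."""


class TooFewRowsError(ChirDeltaError, ValueError):
    """Not enough rows for the requested t-SNE perplexity."""


class AlignmentError(ChirDeltaError, ValueError):
    """Coordinates and records passed to the map exporter do not align."""
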