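"""Exception hierarchy shared across the package."""


class CrisprMfhError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(CrisprMfhError, ValueError):
    """A sequence contains a symbol outside {A, C, G, T, _}."""


class DimensionError(CrisprMfhError, ValueError):
    """Array or sequence dimensions violate an operation's contract."""


class AlignmentError(CrisprMfhError, ValueError):
    """An sgRNA/DNA alignment is structurally invalid (e.g. a double gap)."""


class SchemaError(CrisprMfhError, ValueError):
    """A pair table is missing required columns or has malformed rows."""


class ConfigurationError(CrisprMfhError, ValueError):
    """A model or training configuration violates its invariants."""


class StratificationError(CrisprMfhError, ValueError):
    """Too few minority samples to build the requested stratified folds."""


class FeasibilityError(CrisprMfhError, ValueError):
    """A requested simulation target (e.g. imbalance ratio) is unattainable."""


class TrainingDivergedError(CrisprMfhError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(f"non-finite training loss ({loss!r}) at epoch {epoch}")


class ScoringError(CrisprMfhError, ValueError):
    """A scorer returned non-finite or malformed values."""
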