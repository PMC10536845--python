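"""Exception hierarchy shared across the pipeline stages."""


class QsarScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(QsarScreenError, ValueError):
    """A caller-supplied parameter violates its contract."""


class SchemaError(QsarScreenError, ValueError):
    """An input table is missing required columns, genes or groups."""


class SmilesParseError(QsarScreenError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class DomainError(QsarScreenError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DataError(QsarScreenError, ValueError):
    """Input data is structurally valid but numerically unusable."""


class FitConvergenceError(QsarScreenError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class ProvenanceError(QsarScreenError, RuntimeError):
    """A persisted model's integrity or featurizer provenance check failed."""


class StateError(QsarScreenError, RuntimeError):
    """An operation was invoked on an object in an invalid state."""
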