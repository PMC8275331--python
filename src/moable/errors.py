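"""Exception hierarchy for moable.

Every error raised on purpose by the package derives from :class:`MoableError`
so callers can catch pipeline failures without masking programming errors.
"""


class MoableError(Exception):
    """Base class for all moable errors."""


class FormatError(MoableError):
    """A file does not follow its declared text layout (GCT/GMT/TSV)."""


class GctParseError(FormatError):
    """A GCT cell could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, col: int | None = None):
        self.row = row
        self.col = col
        loc = ""
        if row is not None or col is not None:
            loc = f" (row={row}, col={col})"
        super().__init__(message + loc)


class ValidationError(MoableError):
    """A domain-type invariant is violated (duplicate ids, missing metadata, ...)."""


class SmilesError(MoableError):
    """A SMILES string could not be parsed by the cheminformatics backend."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class FingerprintBackendError(MoableError):
    """No cheminformatics backend available; use precomputed fingerprints."""


class DimensionError(MoableError):
    """Array dimensions do not match what a model or operation expects."""

    def __init__(self, expected, actual, what: str = "input"):
        super().__init__(f"{what} dimension mismatch: expected {expected}, got {actual}")


class ZeroVectorError(MoableError):
    """Cosine similarity requested for an all-zero vector."""


class MissingGeneError(MoableError):
    """A gene has no genetic-perturbation vectors to score against."""
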