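"""Exception hierarchy for the pipeline.

Every error raised by nporigin derives from :class:`NPOriginError` so callers
can catch pipeline failures without masking programming errors.
"""


class NPOriginError(Exception):
    """Base class for all nporigin errors."""


class ConfigurationError(NPOriginError):
    """Invalid configuration (bad probability, grid, kernel spec, ...)."""


class MoleculeParseError(NPOriginError):
    """A SMILES (or SDF record) could not be parsed."""

    def __init__(self, smiles: str, record_id: str | None = None):
        self.smiles = smiles
        self.record_id = record_id
        where = f" (record {record_id})" if record_id else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


class DegenerateInputError(NPOriginError):
    """Input is too small for the operation (e.g. single-atom molecule)."""


class DimensionError(NPOriginError):
    """Mismatched fingerprint dimensionality."""


class UndefinedMetricError(NPOriginError):
    """A metric is undefined for the given confusion matrix."""


class DegenerateTrainingError(NPOriginError):
    """Training data cannot support the model (e.g. a single class)."""


class NotATreeError(NPOriginError):
    """A layout was requested for a graph that is not a forest."""
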