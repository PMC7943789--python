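"""Exception hierarchy shared across the pipeline stages."""


class PhenoscreenError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhenoscreenError, ValueError):
    """An input value lies outside the mathematical domain of an operation
    (nonpositive cell count before a log, mean <= 0 for a Fano factor, ...)."""


class InsufficientDataError(PhenoscreenError, ValueError):
    """Too few observations to compute the requested quantity."""


class NonNormalizableError(PhenoscreenError, ValueError):
    """Control growth rate is <= 0, so the DIP normalization is undefined."""


class DegenerateDatasetError(PhenoscreenError, ValueError):
    """The dataset-wide min(DIP) reference is >= 1: no treatment had any
    effect, so fractions affected are not well posed."""


class UndefinedScoreError(PhenoscreenError, ValueError):
    """The combination fraction affected is 0, so the deviation from Bliss
    independence is undefined (flagged rather than returned as infinity)."""


class GateFitError(PhenoscreenError, RuntimeError):
    """Automatic mixture gating failed; a manual threshold is required."""


class MissingControlError(PhenoscreenError, KeyError):
    """A treated condition has no matched no-compound control. The message
    names the orphan (cell line, MAPK condition, timepoint) combination."""


class SchemaError(PhenoscreenError, ValueError):
    """A tabular input violates the expected schema; the message carries
    row/column coordinates of each violation."""
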