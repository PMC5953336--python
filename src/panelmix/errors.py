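"""Exception and warning types used across panelmix."""


class PanelmixError(Exception):
    """Base class for panelmix errors."""


class ConfigurationError(PanelmixError, ValueError):
    """A layout, model specification, or constraint set is invalid."""


class ValidationError(PanelmixError, ValueError):
    """Input data violate a declared contract (e.g. out-of-range codes)."""


class EstimationError(PanelmixError, RuntimeError):
    """Maximum-likelihood estimation failed (non-convergence, inconsistency)."""


class SparsenessError(EstimationError):
    """Expected cell counts are too sparse to support the requested model.

    Carries the offending cells in ``cells`` as (transition, origin, destination)
    index triples.
    """

    def __init__(self, message, cells=None):
        super().__init__(message)
        self.cells = list(cells) if cells is not None else []


class UnderIdentifiedError(PanelmixError, ValueError):
    """A model has negative residual degrees of freedom."""


class IdentificationWarning(UserWarning):
    """The fit may be under-identified (data/parameter ratio, unreplicated optimum)."""


class UndefinedStatisticWarning(UserWarning):
    """A requested statistic is undefined for the given model (e.g. entropy at S=1)."""
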