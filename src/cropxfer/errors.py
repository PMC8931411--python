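"""Exception hierarchy used across the package."""


class CropXferError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CropXferError):
    """A file or directory does not conform to the expected layout."""


class ValidationError(CropXferError):
    """Input data violates a documented contract (bad labels, bounds, ...)."""


class SizingError(CropXferError):
    """A requested geometry cannot be realised (e.g. too many fields)."""


class InsufficientDataError(CropXferError):
    """Too few valid observations to fit or select a model."""


class CurveFitError(CropXferError):
    """Nonlinear fit failed to converge or produced non-finite parameters."""


class IncomparablePixelError(CropXferError):
    """Two pixels share no usable feature curve."""


class DegenerateDataError(CropXferError):
    """Zero-variance input where a clustering/score is undefined."""


class ContractError(CropXferError):
    """Caller violated an API precondition."""
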