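"""Exception hierarchy for bmquant."""


class BmquantError(Exception):
    """Base class for all bmquant errors."""


class ArgumentError(BmquantError, ValueError):
    """Invalid argument values (shapes, ranges, counts)."""


class UndefinedCorrelationError(BmquantError):
    """Pearson correlation undefined (constant channel within the mask)."""


class DegenerateHistogramError(BmquantError):
    """Otsu thresholding on a constant image."""


class DegenerateMaskError(BmquantError):
    """Overlap fraction with an empty channel mask; carries the areas."""

    def __init__(self, message, area_ch1=0, area_ch2=0, area_overlap=0):
        super().__init__(message)
        self.area_ch1 = area_ch1
        self.area_ch2 = area_ch2
        self.area_overlap = area_overlap


class DivisionByBackgroundError(BmquantError):
    """Reference intensity equals the background at some frame."""


class NoBleachError(BmquantError):
    """Normalization undefined: pre-bleach mean equals the bleach-frame value."""


class FitFailureError(BmquantError):
    """Nonlinear fit did not converge; message carries diagnostics."""


class DegenerateGeometryError(BmquantError):
    """Coincident annotation points make a vertex angle undefined."""


class SchemaError(BmquantError):
    """Malformed tabular input; names the offending row/column."""


class FormatError(BmquantError):
    """Malformed or inconsistent image file."""
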