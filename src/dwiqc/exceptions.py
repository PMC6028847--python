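"""Exception hierarchy for dwiqc.

Every error raised deliberately by the library derives from :class:`DwiqcError`
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class DwiqcError(Exception):
    """Base class for all dwiqc errors."""


class ValidationError(DwiqcError, ValueError):
    """An input violated a documented precondition."""


class GeometryError(DwiqcError, ValueError):
    """Invalid phantom or ROI geometry (overlapping primitives, out-of-grid ROI...)."""


class EmptyROIError(DwiqcError, ValueError):
    """An ROI/VOI selected no (valid) voxels."""


class UndefinedSNRError(DwiqcError, ArithmeticError):
    """The temporal noise image is identically zero; SNR is undefined, not infinite."""


class DegenerateTestError(DwiqcError, ValueError):
    """A statistical test has no information left (e.g. all paired differences zero)."""
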