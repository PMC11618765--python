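"""Exception hierarchy shared across the package."""


class ContourError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(ContourError, ValueError):
    """A polygon or structure violates a geometric invariant."""


class FormatError(ContourError, ValueError):
    """A file does not conform to the expected contour format."""


class ROINotFoundError(ContourError, LookupError):
    """The requested ROI name is absent from an RT Structure Set."""

    def __init__(self, roi_name: str, available: list[str]):
        self.roi_name = roi_name
        self.available = list(available)
        super().__init__(
            f"ROI {roi_name!r} not found; available ROIs: {self.available}"
        )


class DegenerateFitError(ContourError, ValueError):
    """Regression predictor is constant; an OLS line is not identifiable."""


class InfeasibleTargetError(ContourError, ValueError):
    """A simulation target cannot be reached by the shrink construction.

    Attributes
    ----------
    floor : float
        The smallest metric value reachable (DSC as the shrink factor
        approaches zero with the untouched slices kept intact).
    """

    def __init__(self, message: str, floor: float | None = None):
        self.floor = floor
        super().__init__(message)
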