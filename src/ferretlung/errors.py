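"""Exception hierarchy shared across the pipeline.

Exit-code convention for the CLI: 2 for malformed or unusable input,
3 for analyses that are structurally degenerate (nothing wrong with the
file, but the requested estimate is not identifiable from it).
"""


class FerretLungError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(FerretLungError):
    """Invalid parameters, malformed files, or unusable data."""

    exit_code = 2


class NoLungFoundError(InputError):
    """Lung segmentation found no candidate voxels below the threshold."""


class NoExhalationError(InputError):
    """Expiratory trace contains no flow above the noise floor."""


class DegenerateAnalysisError(FerretLungError):
    """The requested estimate is not identifiable from the data provided."""

    exit_code = 3


class CalibrationError(DegenerateAnalysisError):
    """FEV_x calibration criterion never met on the grid.

    Carries the full ratio-vs-x table so the caller can inspect how close
    the controls came to the floor.
    """

    def __init__(self, message, table=None):
        super().__init__(message)
        self.table = table
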