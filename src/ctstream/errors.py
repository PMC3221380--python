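"""Exception hierarchy for the ctstream engine.

Every error a caller may want to handle programmatically has its own class;
all inherit from :class:`CTStreamError` so blanket handling stays possible.
"""


class CTStreamError(Exception):
    """Base class for all ctstream errors."""


# -- volume ingest ----------------------------------------------------------

class InconsistentSeriesError(CTStreamError):
    """Missing or duplicate slice positions in a DICOM series."""


class NonUniformSpacingError(CTStreamError):
    """Inter-slice spacing varies beyond the configured tolerance."""


class HeterogeneousSeriesError(CTStreamError):
    """Slices in one series disagree on image dimensions."""


class InvalidWindowError(CTStreamError):
    """Window width below the minimum of 1 HU."""


class EmptyProbeError(CTStreamError):
    """Probe rectangle does not intersect the slice extent."""


# -- reformatting / rendering ----------------------------------------------

class PlaneOutsideVolumeError(CTStreamError):
    """Requested reformat plane lies outside the volume extent."""


class InvalidZoomError(CTStreamError):
    """Zoom factor must be strictly positive."""


class InvalidCameraError(CTStreamError):
    """Degenerate camera (up parallel to view direction, or zero extent)."""


class UnknownPresetError(CTStreamError):
    """Transfer-function preset name not packaged."""


# -- frame codec ------------------------------------------------------------

class FrameSizeChangedError(CTStreamError):
    """Frame dimensions changed without a codec reset."""


class DecodeFailureError(CTStreamError):
    """A block payload could not be JPEG-decoded.

    Carries the (block_row, block_col) coordinates of the offending block.
    """

    def __init__(self, block_row: int, block_col: int, message: str = ""):
        self.block_row = block_row
        self.block_col = block_col
        super().__init__(
            f"decode failure at block ({block_row}, {block_col})"
            + (f": {message}" if message else "")
        )


class NoTrafficError(CTStreamError):
    """Compression ratio undefined: the encoded frame carries no payload."""


# -- state synchronization ---------------------------------------------------

class StaleDiffError(CTStreamError):
    """Diff base revision does not match the tree revision; full resync needed."""


class UnknownPathError(CTStreamError):
    """Delete addressed a path not present in the tree."""


class DiffParseError(CTStreamError):
    """Malformed state-diff document; carries a location hint."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"parse error{loc}: {message}")


# -- session layer -----------------------------------------------------------

class ConnectionRefusedError_(CTStreamError):
    """Unreachable server or bad credentials."""


class SeriesNotFoundError(CTStreamError):
    """Requested series id not in the server catalog."""


class SessionClosedError(CTStreamError):
    """Operation attempted on a closed session."""


class BadEventError(CTStreamError):
    """Malformed interaction event (unknown kind or wrong payload arity)."""


# -- phantom generation ------------------------------------------------------

class InvalidInsertError(CTStreamError):
    """Lesion insert falls outside the brain mask."""


class InvalidOcclusionError(CTStreamError):
    """Occlusion gap specified without an enclosing vessel."""


# -- reader statistics -------------------------------------------------------

class UndefinedMetricError(CTStreamError):
    """A diagnostic metric has an empty denominator; names the metric."""


class UndefinedKappaError(CTStreamError):
    """Expected agreement is 1 (both raters constant, same category)."""
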