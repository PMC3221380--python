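"""Calibrated CT volumes and quantitative pixel operations.

A directory of single-frame CT DICOM files is reconstructed into an
:class:`ImageVolume`: a 3-D grid of Hounsfield units with physical spacing,
origin and orientation. All quantitative operations (window/level mapping,
HU statistics) run on the original calibrated data, never on display
grayscale — the probe regression tests guard exactly that.

Coordinate conventions
----------------------
Voxel indices are 0-based in ``(slice, row, column)`` order. Patient space
is millimetres, LPS. The orientation matrix stores, as columns, the unit
direction of increasing column index, increasing row index, and the slice
normal. A voxel ``(k, i, j)`` sits at::

    origin + j * spacing_col * col_dir + i * spacing_row * row_dir
           + k * spacing_slice * normal
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    EmptyProbeError,
    HeterogeneousSeriesError,
    InconsistentSeriesError,
    InvalidWindowError,
    NonUniformSpacingError,
)

#: metadata keys retained when the anonymize flag is set
ATTRIBUTE_WHITELIST = (
    "series_description",
    "modality",
    "slice_count",
    "rows",
    "columns",
    "spacing_mm",
    "acquisition_date",
)

DEFAULT_SPACING_TOLERANCE = 0.05


@dataclass
class ImageVolume:
    """A calibrated 3-D Hounsfield-unit grid.

    Attributes
    ----------
    voxels : ndarray, shape (slices, rows, cols)
        Hounsfield units (float32 or integer).
    spacing : tuple of float
        (row, column, slice) spacing in mm, each > 0.
    origin : ndarray, shape (3,)
        Patient-space position of voxel (0, 0, 0) in mm.
    orientation : ndarray, shape (3, 3)
        Columns: column direction, row direction, slice normal (unit, orthogonal).
    modality : str
        "NCCT", "CTA" or "OTHER".
    attributes : dict
        Whitelisted textual metadata.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray
    orientation: np.ndarray
    modality: str = "OTHER"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (slices, rows, cols)")
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        m = self.orientation
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-6):
            raise ValueError("orientation columns must be orthonormal")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def col_dir(self) -> np.ndarray:
        return self.orientation[:, 0]

    @property
    def row_dir(self) -> np.ndarray:
        return self.orientation[:, 1]

    @property
    def slice_normal(self) -> np.ndarray:
        return self.orientation[:, 2]

    def index_to_patient(self, k: float, i: float, j: float) -> np.ndarray:
        """Patient-space mm position of (possibly fractional) voxel index."""
        sr, sc, ss = self.spacing
        return (
            self.origin
            + j * sc * self.col_dir
            + i * sr * self.row_dir
            + k * ss * self.slice_normal
        )

    def patient_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map patient-space mm points (..., 3) to fractional (k, i, j)."""
        pts = np.asarray(points, dtype=float)
        rel = pts - self.origin
        # orientation is orthonormal: projection by dot products
        sr, sc, ss = self.spacing
        j = rel @ self.col_dir / sc
        i = rel @ self.row_dir / sr
        k = rel @ self.slice_normal / ss
        return np.stack([k, i, j], axis=-1)

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size (slice, row, col axes) in mm."""
        sr, sc, ss = self.spacing
        ns, nr, nc = self.voxels.shape
        return ((ns - 1) * ss, (nr - 1) * sr, (nc - 1) * sc)


@dataclass(frozen=True)
class WindowLevel:
    """Display window: ``center`` (level) and ``width`` in HU, width >= 1."""

    center: float
    width: float

    def __post_init__(self):
        if self.width < 1:
            raise InvalidWindowError(f"invalid window: width {self.width} < 1")


@dataclass(frozen=True)
class HUProbe:
    """Statistics of original HU values inside a rectangular probe region."""

    region: tuple[int, int, int, int]  # (row0, col0, n_rows, n_cols), clipped
    mean: float
    sd: float
    min: float
    max: float
    count: int


# ---------------------------------------------------------------------------
# series loading
# ---------------------------------------------------------------------------

def _read_datasets(directory_path, series_selector=None):
    directory = Path(directory_path)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue  # non-DICOM clutter is skipped silently
        uid = getattr(ds, "SeriesInstanceUID", None)
        if series_selector is not None and uid != series_selector:
            continue
        datasets.append(ds)
    return datasets


def load_series(
    directory_path,
    series_selector: str | None = None,
    *,
    anonymize: bool = True,
    spacing_tolerance: float = DEFAULT_SPACING_TOLERANCE,
) -> ImageVolume:
    """Load a single-frame CT DICOM series into a calibrated volume.

    Slices are sorted by the projection of their image position onto the
    slice normal; rescale slope/intercept turn stored values into HU.

    Parameters
    ----------
    directory_path : path-like
        Directory of DICOM Part-10 files.
    series_selector : str, optional
        SeriesInstanceUID to select when the directory mixes series.
    anonymize : bool
        When true (default) only whitelisted textual attributes are kept.
    spacing_tolerance : float
        Maximum allowed relative deviation of inter-slice gaps.

    Raises
    ------
    InconsistentSeriesError, NonUniformSpacingError, HeterogeneousSeriesError
    """
    datasets = _read_datasets(directory_path, series_selector)
    if len(datasets) < 2:
        raise InconsistentSeriesError(
            f"inconsistent series: found {len(datasets)} DICOM slices, need >= 2"
        )

    first = datasets[0]
    iop = [float(v) for v in first.ImageOrientationPatient]
    col_dir = np.array(iop[:3])  # direction of increasing column index
    row_dir = np.array(iop[3:])  # direction of increasing row index
    normal = np.cross(col_dir, row_dir)

    shape0 = (int(first.Rows), int(first.Columns))
    keyed = []
    for ds in datasets:
        if (int(ds.Rows), int(ds.Columns)) != shape0:
            raise HeterogeneousSeriesError(
                "heterogeneous series: mixed image dimensions"
            )
        pos = np.array([float(v) for v in ds.ImagePositionPatient])
        keyed.append((float(pos @ normal), ds))
    keyed.sort(key=lambda kv: kv[0])

    zs = np.array([z for z, _ in keyed])
    gaps = np.diff(zs)
    if np.any(gaps <= 0):
        raise InconsistentSeriesError(
            "inconsistent series: duplicate or non-monotonic slice positions"
        )
    mean_gap = float(gaps.mean())
    if np.max(np.abs(gaps - mean_gap)) > spacing_tolerance * mean_gap:
        raise NonUniformSpacingError(
            f"non-uniform spacing: gaps deviate more than "
            f"{spacing_tolerance:.0%} from mean {mean_gap:.3f} mm"
        )

    slices = []
    for _, ds in keyed:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float32) * slope + intercept
        slices.append(arr)
    voxels = np.stack(slices, axis=0)
    if np.allclose(voxels, np.round(voxels)):
        voxels = np.round(voxels).astype(np.int16)

    ps = [float(v) for v in first.PixelSpacing]  # (row, col)
    spacing = (ps[0], ps[1], mean_gap)
    origin = np.array([float(v) for v in keyed[0][1].ImagePositionPatient])
    orientation = np.column_stack([col_dir, row_dir, normal])

    desc = str(getattr(first, "SeriesDescription", ""))
    modality = "OTHER"
    if "CTA" in desc.upper():
        modality = "CTA"
    elif "NCCT" in desc.upper() or "HEAD" in desc.upper() or "BRAIN" in desc.upper():
        modality = "NCCT"

    attributes = {
        "series_description": desc,
        "modality": str(getattr(first, "Modality", "CT")),
        "slice_count": len(keyed),
        "rows": shape0[0],
        "columns": shape0[1],
        "spacing_mm": [round(s, 6) for s in spacing],
        "acquisition_date": str(getattr(first, "AcquisitionDate", "")),
    }
    if not anonymize:
        attributes["patient_name"] = str(getattr(first, "PatientName", ""))
        attributes["patient_id"] = str(getattr(first, "PatientID", ""))

    return ImageVolume(
        voxels=voxels,
        spacing=spacing,
        origin=origin,
        orientation=orientation,
        modality=modality,
        attributes=attributes,
    )


def write_series(
    volume: ImageVolume,
    directory_path,
    *,
    series_description: str = "",
    patient_name: str = "",
    rescale_intercept: float = -1024.0,
    shuffle_seed: int | None = None,
) -> str:
    """Write a volume as single-frame CT DICOM files; returns the series UID.

    Stored values are ``HU - rescale_intercept`` as unsigned 16-bit, so
    integer-valued phantoms round-trip exactly through :func:`load_series`.
    With ``shuffle_seed`` the on-disk file order is randomized (slice
    positions still identify the geometry).
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()

    order = np.arange(volume.n_slices)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(order)

    for file_idx, k in enumerate(order):
        k = int(k)
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series_description or volume.modality
        ds.PatientName = patient_name
        ds.PatientID = "P0" if patient_name else ""
        ds.AcquisitionDate = datetime.date.today().strftime("%Y%m%d")
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = volume.voxels.shape[1:]
        ds.PixelSpacing = [volume.spacing[0], volume.spacing[1]]
        ds.SliceThickness = volume.spacing[2]
        pos = volume.index_to_patient(k, 0, 0)
        ds.ImagePositionPatient = [float(v) for v in pos]
        iop = list(volume.col_dir) + list(volume.row_dir)
        ds.ImageOrientationPatient = [float(v) for v in iop]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = float(rescale_intercept)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        stored = np.round(
            volume.voxels[k].astype(np.float64) - rescale_intercept
        )
        stored = np.clip(stored, 0, 65535).astype(np.uint16)
        ds.PixelData = stored.tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(
            directory / f"slice_{file_idx:04d}.dcm", ds, enforce_file_format=True
        )
    return series_uid


# ---------------------------------------------------------------------------
# quantitative pixel operations
# ---------------------------------------------------------------------------

def apply_window(image_2d: np.ndarray, wl: WindowLevel) -> np.ndarray:
    """Map an HU image to 8-bit grayscale with the standard linear window.

    Uses the DICOM-style linear mapping

        out = clamp(((v - (c - 0.5)) / (w - 1) + 0.5) * 255, 0, 255)

    rounded half-up; a width of 1 degenerates to a binary threshold at the
    center. Monotone non-decreasing in the input by construction.
    """
    if wl.width < 1:
        raise InvalidWindowError("invalid window")
    v = np.asarray(image_2d, dtype=np.float64)
    if wl.width == 1:
        out = np.where(v < wl.center, 0.0, 255.0)
    else:
        out = ((v - (wl.center - 0.5)) / (wl.width - 1) + 0.5) * 255.0
    out = np.clip(out, 0.0, 255.0)
    return np.floor(out + 0.5).astype(np.uint8)  # round half-up


def hu_probe(
    volume: ImageVolume,
    slice_index: int,
    rectangle: tuple[int, int, int, int],
) -> HUProbe:
    """HU statistics over a rectangle of one stored slice.

    ``rectangle`` is (row0, col0, n_rows, n_cols) in voxel units; the part
    outside the slice is clipped. Statistics use the original HU voxels.
    """
    if not 0 <= slice_index < volume.n_slices:
        raise EmptyProbeError("empty probe region: slice index outside volume")
    r0, c0, nr, nc = rectangle
    r1, c1 = r0 + nr, c0 + nc
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c = min(r1, volume.voxels.shape[1])
    c1c = min(c1, volume.voxels.shape[2])
    if r1c <= r0c or c1c <= c0c:
        raise EmptyProbeError("empty probe region")
    region = volume.voxels[slice_index, r0c:r1c, c0c:c1c].astype(np.float64)
    return HUProbe(
        region=(r0c, c0c, r1c - r0c, c1c - c0c),
        mean=float(region.mean()),
        sd=float(region.std(ddof=0)),
        min=float(region.min()),
        max=float(region.max()),
        count=int(region.size),
    )
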