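"""Reading, writing, and rasterizing contour structures.

Two on-disk formats are supported:

* DICOM RT Structure Set (the clinical interchange format) — contours are
  stored as CLOSED_PLANAR items whose ContourData is a flat sequence of
  (x, y, z) triplets in patient mm.
* A plain JSON dialect for fixtures and pipelines::

      {"schema_version": 1, "name": ..., "slice_thickness": ...,
       "slices": [{"z": ..., "points": [[x, y, z], ...]}, ...]}

Rasterization converts a structure to a per-plane binary mask on a regular
grid (pixel-center inclusion, boundary counts as inside), which is the
substrate for the volumetric Dice coefficient.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pydicom
import shapely
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.sequence import Sequence
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .contour_model import SliceContour, Structure
from .errors import FormatError, GeometryError, ROINotFoundError

_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
JSON_SCHEMA_VERSION = 1

#: z values closer than this are treated as the same plane when merging (mm)
_Z_MERGE_TOL = 1e-6


# ---------------------------------------------------------------------------
# Raster grid
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RasterGrid:
    """A regular in-plane grid replicated on a set of axial planes.

    ``origin`` is the center of pixel (row 0, col 0); x increases with
    column index and y with row index; ``pixel_size`` is isotropic in-plane.
    """

    origin: tuple[float, float]
    pixel_size: float
    shape: tuple[int, int]  # (rows, cols)
    z_planes: tuple[float, ...]

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise GeometryError("grid shape must be positive")
        zs = np.asarray(self.z_planes, dtype=float)
        if len(zs) > 1 and np.min(np.diff(zs)) <= 0:
            raise GeometryError("z_planes must be strictly increasing")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) coordinates of all pixel centers on one plane."""
        rows, cols = self.shape
        xs = self.origin[0] + np.arange(cols) * self.pixel_size
        ys = self.origin[1] + np.arange(rows) * self.pixel_size
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()

    @classmethod
    def cover(
        cls,
        structures,
        pixel_size: float = 1.0,
        margin: float = 2.0,
    ) -> "RasterGrid":
        """Build a grid covering one or more structures with a margin (mm).

        The z planes are the merged union of all slice positions (positions
        within 1e-6 mm collapse to one plane).
        """
        structures = list(structures)
        if not structures or any(not s.slices for s in structures):
            raise GeometryError("cannot build a grid over an empty structure")
        boxes = np.array([s.bounds() for s in structures])
        x0 = boxes[:, 0].min() - margin
        y0 = boxes[:, 1].min() - margin
        x1 = boxes[:, 2].max() + margin
        y1 = boxes[:, 3].max() + margin
        cols = int(np.ceil((x1 - x0) / pixel_size)) + 1
        rows = int(np.ceil((y1 - y0) / pixel_size)) + 1
        zs: list[float] = []
        for s in structures:
            for z in s.z_values:
                if not any(abs(z - p) <= _Z_MERGE_TOL for p in zs):
                    zs.append(float(z))
        return cls((x0, y0), pixel_size, (rows, cols), tuple(sorted(zs)))


def rasterize_slice(contour: SliceContour, grid: RasterGrid) -> np.ndarray:
    """Binary mask of one slice polygon on the grid's in-plane lattice.

    A pixel is inside when its center lies inside the polygon; centers
    exactly on an edge count as inside.
    """
    gx, gy = grid.pixel_centers()
    inside = shapely.intersects_xy(contour.polygon, gx, gy)
    return inside.reshape(grid.shape)


def rasterize(s: Structure, grid: RasterGrid) -> np.ndarray:
    """Rasterize a structure to a (n_planes, rows, cols) boolean volume.

    Every slice of the structure must match a grid plane within half the
    slice thickness; grid planes without a matching slice are all-zero.
    """
    planes = np.asarray(grid.z_planes, dtype=float)
    vol = np.zeros((len(planes), *grid.shape), dtype=bool)
    half = s.slice_thickness / 2.0
    for sl in s.slices:
        d = np.abs(planes - sl.z)
        k = int(np.argmin(d))
        if d[k] > half:
            raise GeometryError(
                f"slice at z={sl.z:g} mm has no grid plane within {half:g} mm"
            )
        vol[k] |= rasterize_slice(sl, grid)
    return vol


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------
def write_json_contours(s: Structure, path) -> None:
    """Write a structure to the JSON fixture dialect (lossless)."""
    doc = {
        "schema_version": JSON_SCHEMA_VERSION,
        "name": s.name,
        "slice_thickness": s.slice_thickness,
        "slices": [
            {"z": sl.z, "points": sl.points.tolist()} for sl in s.slices
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_json_contours(path) -> Structure:
    """Read a structure from the JSON fixture dialect.

    Unsorted slices are accepted (sorted on ingest, with a warning);
    structural schema violations raise :class:`FormatError`.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "slices" not in doc or "name" not in doc:
        raise FormatError("JSON contour file missing required keys")
    try:
        slices = [SliceContour(np.asarray(item["points"], dtype=float))
                  for item in doc["slices"]]
        thickness = float(doc.get("slice_thickness", 3.0))
    except (KeyError, TypeError, GeometryError) as exc:
        raise FormatError(f"malformed JSON contour file: {exc}") from exc
    zs = [sl.z for sl in slices]
    if zs != sorted(zs):
        warnings.warn("slices were not sorted by z; sorting on ingest")
    return Structure(str(doc["name"]), slices, thickness)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set
# ---------------------------------------------------------------------------
def write_rtstruct(s: Structure, path, ref_meta: dict | None = None) -> None:
    """Write a structure as a minimal DICOM RT Structure Set.

    When no reference CT metadata is supplied, a synthetic FrameOfReference
    is embedded so the file is self-contained and re-readable.  Coordinates
    are written with 6 decimals (DICOM DS), i.e. round-trip to <1e-6 mm.
    """
    if not s.slices:
        raise FormatError("refusing to write an empty structure")
    ref_meta = ref_meta or {}
    frame_uid = ref_meta.get("frame_of_reference_uid", generate_uid())

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = ref_meta.get("patient_name", "SYNTHETIC^PHANTOM")
    ds.PatientID = ref_meta.get("patient_id", "PHANTOM000")
    now = datetime.datetime.now()
    ds.StructureSetDate = now.strftime("%Y%m%d")
    ds.StructureSetTime = now.strftime("%H%M%S")
    ds.StructureSetLabel = s.name[:16]

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = Sequence([ref_frame])

    roi = Dataset()
    roi.ROINumber = 1
    roi.ReferencedFrameOfReferenceUID = frame_uid
    roi.ROIName = s.name
    roi.ROIGenerationAlgorithm = "AUTOMATIC"
    ds.StructureSetROISequence = Sequence([roi])

    contour_items = []
    for sl in s.slices:
        pts = sl.points
        if sl.was_clockwise:  # restore the ingested orientation on write
            pts = np.roll(pts[::-1], 1, axis=0)
        item = Dataset()
        item.ContourGeometricType = "CLOSED_PLANAR"
        item.NumberOfContourPoints = sl.n_points
        item.ContourData = [f"{v:.6f}" for v in pts.ravel()]
        contour_items.append(item)
    roi_contour = Dataset()
    roi_contour.ReferencedROINumber = 1
    roi_contour.ROIDisplayColor = [255, 128, 0]
    roi_contour.ContourSequence = Sequence(contour_items)
    ds.ROIContourSequence = Sequence([roi_contour])

    obs = Dataset()
    obs.ObservationNumber = 1
    obs.ReferencedROINumber = 1
    obs.RTROIInterpretedType = "ORGAN"
    ds.RTROIObservationsSequence = Sequence([obs])

    pydicom.dcmwrite(str(path), ds)


def read_rtstruct(path, roi_name: str, slice_thickness: float | None = None) -> Structure:
    """Read one named ROI from a DICOM RT Structure Set.

    Point order is preserved as stored.  ``slice_thickness`` defaults to
    the median z-gap between contour items (3.0 mm for a single slice).
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise FormatError(f"{path} is not an RT Structure Set")
    names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)
    if roi_name not in names.values():
        raise ROINotFoundError(roi_name, sorted(names.values()))
    number = next(k for k, v in names.items() if v == roi_name)
    contour_seq = None
    for rc in getattr(ds, "ROIContourSequence", []):
        if int(rc.ReferencedROINumber) == number:
            contour_seq = getattr(rc, "ContourSequence", Sequence())
            break
    if contour_seq is None:
        raise FormatError(f"ROI {roi_name!r} has no contour data")
    slices = []
    for item in contour_seq:
        gtype = str(item.ContourGeometricType)
        if gtype != "CLOSED_PLANAR":
            raise FormatError(
                f"unsupported contour geometric type {gtype!r}; "
                "only CLOSED_PLANAR is supported"
            )
        data = np.asarray([float(v) for v in item.ContourData], dtype=float)
        if data.size % 3:
            raise FormatError("ContourData length is not a multiple of 3")
        pts = data.reshape(-1, 3)
        if np.ptp(pts[:, 2]) > 1e-6:
            raise FormatError(
                f"non-planar contour item (z spans {np.ptp(pts[:, 2]):g} mm)"
            )
        pts[:, 2] = pts[0, 2]
        slices.append(SliceContour(pts))
    slices.sort(key=lambda sl: sl.z)
    if slice_thickness is None:
        zs = [sl.z for sl in slices]
        slice_thickness = float(np.median(np.diff(zs))) if len(zs) > 1 else 3.0
    return Structure(roi_name, slices, slice_thickness)


def read_structure(path, roi_name: str | None = None) -> Structure:
    """Dispatch on file extension: ``.json`` → JSON dialect, else DICOM."""
    p = str(path)
    if p.lower().endswith(".json"):
        return read_json_contours(p)
    if roi_name is None:
        raise FormatError("reading an RT-STRUCT requires an ROI name")
    return read_rtstruct(p, roi_name)
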