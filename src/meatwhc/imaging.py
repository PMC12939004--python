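"""DICOM reading, slice-quality scoring and grayscale matrix export.

A T2-weighted scan yields several slices per sample; slices whose
muscle contour is cut off by the field of view (or fragmented) bias
pixel-level features, so one complete slice per sample is selected by
an explicit, reproducible criterion: the foreground (pixels above a
fraction of the slice maximum) is labeled into 8-connected components,
and a slice qualifies when its largest component does not touch the
image border.  Among qualifying slices the one with the largest
foreground component wins; ties go to the lowest slice index.

Matrices can be exported in the plain tab-delimited text dialect
(one row per line, no header) and written as minimal single-frame
16-bit DICOM files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from skimage.measure import label as _cc_label

__all__ = [
    "GrayMatrix",
    "SliceSelection",
    "read_dicom_slice",
    "write_dicom_slice",
    "completeness_score",
    "select_best_slice",
    "export_gray_text",
    "read_gray_text",
]

#: 8-connectivity for component labeling (scikit-image connectivity=2).
CONNECTIVITY = 2

#: Default foreground threshold as a fraction of the slice maximum.
DEFAULT_THRESHOLD_FRACTION = 0.2


@dataclass(frozen=True)
class GrayMatrix:
    """One grayscale MRI slice: nonnegative intensities, row-major."""

    values: np.ndarray
    source_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={v.ndim}")
        if np.any(v < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SliceSelection:
    """Outcome of scoring/selecting a slice.

    ``completeness_score`` is the fraction of foreground pixels in the
    largest connected component (1.0 when the foreground is a single
    blob); ``flagged`` marks a sample where no border-free slice exists
    and a manual check is advised.
    """

    chosen_index: int
    completeness_score: float
    touches_border: bool
    foreground_area: int
    flagged: bool = False


def read_dicom_slice(path: str | Path) -> GrayMatrix:
    """Read a single-frame grayscale DICOM file, preserving stored values.

    Integer stored values are converted losslessly to float64.  A
    non-identity rescale slope/intercept is applied with a warning;
    no windowing or normalization is ever performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ValueError(f"{path}: not a grayscale image")
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames != 1:
        raise ValueError(f"{path}: expected a single frame, got {n_frames}")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        warnings.warn(
            f"{path}: non-identity rescale (slope={slope}, intercept={intercept}) applied",
            stacklevel=2,
        )
        arr = arr * slope + intercept
    idx = int(getattr(ds, "InstanceNumber", 1)) - 1
    return GrayMatrix(values=arr, source_id=path.stem, slice_index=max(idx, 0))


def write_dicom_slice(m: GrayMatrix, path: str | Path) -> Path:
    """Write a minimal single-frame 16-bit unsigned DICOM file.

    Values are rounded to the nearest integer and clipped to the
    uint16 range; no rescale slope/intercept is set, so integer-valued
    matrices round-trip exactly.  UIDs are derived from the source id
    and slice index, keeping output byte-reproducible.
    """
    path = Path(path)
    pixels = np.clip(np.rint(m.values), 0, 65535).astype("<u2")
    rows, cols = pixels.shape

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[m.source_id, str(m.slice_index)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), Dataset(), file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[m.source_id])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[m.source_id, "study"])
    ds.PatientName = m.source_id or "phantom"
    ds.PatientID = m.source_id or "phantom"
    ds.InstanceNumber = m.slice_index + 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = rows
    ds.Columns = cols
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def _score(values: np.ndarray, threshold_fraction: float) -> tuple[float, bool, int]:
    vmax = values.max()
    if vmax <= 0:
        return 0.0, False, 0
    fg = values >= threshold_fraction * vmax
    total = int(fg.sum())
    if total == 0:
        return 0.0, False, 0
    labels = _cc_label(fg, connectivity=CONNECTIVITY)
    areas = np.bincount(labels.ravel())[1:]
    biggest = int(areas.argmax()) + 1
    comp = labels == biggest
    touches = bool(comp[0, :].any() or comp[-1, :].any()
                   or comp[:, 0].any() or comp[:, -1].any())
    area = int(areas.max())
    return area / total, touches, area


def completeness_score(m: GrayMatrix,
                       threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                       ) -> SliceSelection:
    """Score one slice's contour completeness.

    Foreground = pixels at or above ``threshold_fraction`` of the slice
    maximum.  The score is the largest 8-connected component's share of
    all foreground pixels; a component meeting the first/last row or
    column marks the contour as truncated.  An all-zero image scores 0.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    score, touches, area = _score(m.values, threshold_fraction)
    return SliceSelection(chosen_index=m.slice_index, completeness_score=score,
                          touches_border=touches, foreground_area=area)


def select_best_slice(slices: list[GrayMatrix],
                      threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                      ) -> SliceSelection:
    """Pick one slice per sample: complete contour first, then size.

    Among slices whose largest foreground component avoids the border,
    the one with the largest component wins (lowest slice_index on
    ties).  If every slice touches the border, the highest completeness
    score wins and the result is flagged for manual review.
    """
    if not slices:
        raise ValueError("select_best_slice requires at least one slice")
    scored = [completeness_score(m, threshold_fraction) for m in slices]
    clean = [s for s in scored if not s.touches_border]
    if clean:
        best = max(clean, key=lambda s: (s.foreground_area, -s.chosen_index))
        return best
    best = max(scored, key=lambda s: (s.completeness_score, -s.chosen_index))
    return SliceSelection(chosen_index=best.chosen_index,
                          completeness_score=best.completeness_score,
                          touches_border=best.touches_border,
                          foreground_area=best.foreground_area,
                          flagged=True)


def export_gray_text(m: GrayMatrix, path: str | Path) -> Path:
    """Write the matrix as tab-delimited text: one row per line, no header.

    Values are written with repr-exact precision (``%.17g``) and a
    trailing newline after the last row, so integer-valued and general
    float64 matrices both round-trip exactly through ``read_gray_text``.
    """
    if not str(path):
        raise ValueError("empty output path")
    path = Path(path)
    np.savetxt(path, m.values, fmt="%.17g", delimiter="\t")
    return path


def read_gray_text(path: str | Path, source_id: str = "",
                   slice_index: int = 0) -> GrayMatrix:
    """Parse a tab-delimited matrix written by :func:`export_gray_text`."""
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return GrayMatrix(values=values, source_id=source_id or Path(path).stem,
                      slice_index=slice_index)
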