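"""Image containers and readers/writers.

Conventions
-----------
* ``ImageVolume.data`` is indexed ``[i, j, k]``; world position of a voxel
  center is ``origin + orientation @ (spacing * index)`` (mm).  The default
  orientation is the identity, i.e. axes aligned with the phantom frame
  (+X left, +Y down, +Z superior).
* NIfTI files are written losslessly (float32) with a JSON sidecar carrying
  the timing metadata (TR/TE/TI/flip).  DICOM files are one-per-slice,
  magnitude stored as 16-bit integers with rescale slope/intercept.
* Voxel indices are 0-based everywhere; reports state the frame of every
  coordinate they contain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_META_KEYS = ("TR", "TE", "TI", "flip", "series", "repeat")


@dataclass
class ImageVolume:
    """3D scalar image + geometry + acquisition metadata."""

    data: np.ndarray                # shape (nx, ny, nz), float
    spacing: tuple[float, float, float]          # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)   # mm, voxel (0,0,0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        q = np.asarray(self.orientation, dtype=float)
        if not np.allclose(q @ q.T, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be orthonormal")
        self.orientation = q

    # -- coordinate transforms -------------------------------------------
    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        xyz = idx * np.asarray(self.spacing)
        return (xyz @ self.orientation.T) + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float)) - np.asarray(self.origin)
        return (xyz @ self.orientation) / np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = self.orientation * np.asarray(self.spacing)
        a[:3, 3] = self.origin
        return a


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(vol: ImageVolume, path) -> Path:
    """Write one volume as float32 NIfTI-1 plus a JSON sidecar with metadata."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))
    side = {k: vol.meta[k] for k in _META_KEYS if k in vol.meta}
    base = str(path)
    for suf in (".nii.gz", ".nii"):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    Path(base + ".json").write_text(json.dumps(side, indent=1))
    return path


def read_nifti(path) -> ImageVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(np.linalg.norm(aff[:3, :3], axis=0))
    orientation = aff[:3, :3] / np.asarray(spacing)
    meta = {}
    base = str(path)
    for suf in (".nii.gz", ".nii"):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    side = Path(base + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return ImageVolume(
        np.asarray(img.dataobj, dtype=float), spacing, tuple(aff[:3, 3]),
        orientation, meta,
    )


# ---------------------------------------------------------------------------
# DICOM (one file per slice along the third index)
# ---------------------------------------------------------------------------

def write_dicom_series(vol: ImageVolume, directory, series_number: int = 1) -> list:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = vol.data
    lo, hi = float(data.min()), float(data.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    stored = np.round((data - lo) / slope).astype(np.uint16)

    series_uid = generate_uid()
    files = []
    for k in range(data.shape[2]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = pydicom.uid.MRImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = series_number
        ds.InstanceNumber = k + 1
        ds.SeriesDescription = str(vol.meta.get("series", "sysphantom"))
        # pixel array rows=j, cols=i; slice = fixed k
        sl = stored[:, :, k].T  # rows along j, cols along i
        ds.Rows, ds.Columns = sl.shape
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.SpacingBetweenSlices = float(vol.spacing[2])
        pos = vol.index_to_world([0, 0, k])[0]
        ds.ImagePositionPatient = [float(v) for v in pos]
        row_dir = vol.orientation[:, 0]   # direction of increasing column (i)
        col_dir = vol.orientation[:, 1]   # direction of increasing row (j)
        ds.ImageOrientationPatient = [float(v) for v in np.r_[row_dir, col_dir]]
        if "TR" in vol.meta:
            ds.RepetitionTime = float(vol.meta["TR"])
        if "TE" in vol.meta:
            ds.EchoTime = float(vol.meta["TE"])
        if vol.meta.get("TI") is not None:
            ds.InversionTime = float(vol.meta["TI"])
        if vol.meta.get("flip") is not None:
            ds.FlipAngle = float(vol.meta["flip"])
        ds.RescaleSlope = slope
        ds.RescaleIntercept = lo
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = sl.tobytes()
        fname = directory / f"slice{k:04d}.dcm"
        ds.save_as(str(fname), enforce_file_format=True)
        files.append(fname)
    return files


def read_dicom_series(directory) -> list[ImageVolume]:
    """Read all DICOM series under a directory, one ImageVolume per series."""
    import pydicom

    directory = Path(directory)
    by_series: dict[str, list] = {}
    for f in sorted(directory.rglob("*.dcm")):
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # pragma: no cover - corrupt file contract
            raise IOError(f"cannot read DICOM file {f}: {exc}") from exc
        by_series.setdefault(str(ds.SeriesInstanceUID), []).append(ds)
    vols = []
    for uid, dss in by_series.items():
        dss.sort(key=lambda d: int(d.InstanceNumber))
        slices = []
        for d in dss:
            arr = d.pixel_array.astype(float)
            arr = arr * float(getattr(d, "RescaleSlope", 1.0)) + float(
                getattr(d, "RescaleIntercept", 0.0))
            slices.append(arr.T)  # back to [i, j]
        data = np.stack(slices, axis=2)
        d0 = dss[0]
        ps = [float(v) for v in d0.PixelSpacing]
        spacing = (ps[1], ps[0], float(getattr(d0, "SpacingBetweenSlices",
                                                getattr(d0, "SliceThickness", 1.0))))
        iop = [float(v) for v in d0.ImageOrientationPatient]
        orient = np.eye(3)
        orient[:, 0] = iop[:3]
        orient[:, 1] = iop[3:]
        orient[:, 2] = np.cross(iop[:3], iop[3:])
        meta = {"series": str(getattr(d0, "SeriesDescription", ""))}
        for tag, key in (("RepetitionTime", "TR"), ("EchoTime", "TE"),
                         ("InversionTime", "TI"), ("FlipAngle", "flip")):
            if hasattr(d0, tag):
                meta[key] = float(getattr(d0, tag))
        vols.append(ImageVolume(data, spacing,
                                tuple(float(v) for v in d0.ImagePositionPatient),
                                orient, meta))
    return vols


def _sort_key(vol: ImageVolume):
    m = vol.meta
    for k in ("TI", "TE", "flip"):
        if m.get(k) is not None:
            return (k, float(m[k]))
    return ("z", 0.0)


def read_series(path) -> list[ImageVolume]:
    """Read a directory of DICOM files or NIfTI volumes (+ JSON sidecars).

    Volumes are sorted by TI, TE, or flip angle (whichever is present) and
    geometry is validated to be consistent across the series.
    """
    path = Path(path)
    if path.is_file():
        vols = [read_nifti(path)]
    else:
        niftis = sorted(list(path.glob("*.nii")) + list(path.glob("*.nii.gz")))
        if niftis:
            vols = [read_nifti(f) for f in niftis]
        else:
            vols = read_dicom_series(path)
    if not vols:
        raise IOError(f"no images found under {path}")
    vols.sort(key=_sort_key)
    ref = vols[0]
    for v in vols[1:]:
        if v.data.shape != ref.data.shape or not np.allclose(v.spacing, ref.spacing):
            raise ValueError("mixed geometry within a series")
    missing = [i for i, v in enumerate(vols)
               if len(vols) > 1 and _sort_key(v)[0] == "z"]
    if missing:
        warnings.warn(f"{len(missing)} volumes lack TI/TE/flip metadata; "
                      "series order falls back to file order")
    return vols
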