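"""Scan volume and fiducial-spec I/O.

Internal convention: a scan is a 3-D array ordered ``(z, y, x)`` with the
slice axis first (the segmentation is defined layer-by-layer, so the
slice axis must be explicit), 0-based indices everywhere, and intensities
carried as-is in arbitrary MPI units — no rescaling on load, since MPI
intensity is linear in iron and rescaling would silently change the
calibration.

Supported formats: NIfTI-1 (reference format), multi-page TIFF, and a
minimal read-only DICOM series (single-frame files sorted by instance
number).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ScanVolume",
    "FiducialSpec",
    "read_scan",
    "write_scan",
    "read_fiducials",
    "write_report",
]

DEFAULT_SEARCH_RADIUS = 5.0


@dataclass
class ScanVolume:
    """A 3-D MPI intensity grid with voxel geometry and metadata.

    ``voxels`` is ordered (slice z, row y, col x); ``voxel_size`` is mm
    per axis in the same order; ``meta`` carries subject id, timepoint
    and modality tags.
    """

    voxels: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"scan volume must be 3-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("scan volume contains non-finite values")
        self.voxels = v

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class FiducialSpec:
    """Expected location and known composition of one fiducial marker.

    The iron mass of the marker is ``concentration_fraction x
    stock_iron_mg_per_ml x volume_ul`` micrograms (mg/ml x ul = ug).
    """

    id: str
    expected_center: tuple
    concentration_fraction: float
    stock_iron_mg_per_ml: float
    volume_ul: float
    search_radius: float = DEFAULT_SEARCH_RADIUS

    def __post_init__(self):
        if not (0.0 < self.concentration_fraction <= 1.0):
            raise ValueError(
                f"fiducial {self.id!r}: concentration_fraction must be in (0, 1], "
                f"got {self.concentration_fraction}"
            )
        if self.stock_iron_mg_per_ml <= 0 or self.volume_ul <= 0:
            raise ValueError(
                f"fiducial {self.id!r}: stock concentration and volume must be > 0"
            )
        if self.search_radius <= 0:
            raise ValueError(f"fiducial {self.id!r}: search_radius must be > 0")
        if len(self.expected_center) != 3:
            raise ValueError(f"fiducial {self.id!r}: expected_center must be (z, y, x)")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if path.is_dir() or name.endswith(".dcm"):
        return "dicom_series"
    raise ValueError(f"cannot infer scan format from {path}")


def read_scan(path, format: str | None = None) -> ScanVolume:
    """Read a scan volume, normalising axis order to (z, y, x).

    ``format`` is one of ``nifti``, ``tiff_stack``, ``dicom_series``; when
    omitted it is inferred from the path.  Voxel size is taken from the
    header when present, else 1 mm isotropic with a warning.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "tiff_stack":
        return _read_tiff(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown scan format {fmt!r}")


def _read_nifti(path: Path) -> ScanVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 2:
        raise ValueError(f"{path}: 2-D image; a 3-D volume is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    # NIfTI stores (x, y, z); internal order is (z, y, x)
    vox = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ScanVolume(voxels=vox, voxel_size=voxel_size, meta={"source": str(path)})


def _read_tiff(path: Path) -> ScanVolume:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    if data.ndim == 2:
        raise ValueError(f"{path}: single-page TIFF; a multi-page stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a page stack, got shape {data.shape}")
    voxel_size = None
    if desc:
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict) and "voxel_size" in meta:
                voxel_size = tuple(float(v) for v in meta["voxel_size"])
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    if voxel_size is None:
        warnings.warn(f"{path}: no voxel size in TIFF metadata; assuming 1 mm isotropic")
        voxel_size = (1.0, 1.0, 1.0)
    return ScanVolume(voxels=data.astype(float), voxel_size=voxel_size, meta={"source": str(path)})


def _read_dicom_series(path: Path) -> ScanVolume:
    import pydicom

    path = Path(path)
    files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"{path}: no DICOM files found")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    if len(datasets) < 2:
        raise ValueError(f"{path}: DICOM series needs >= 2 slices, got {len(datasets)}")
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = [d.pixel_array.astype(float) for d in datasets]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"{path}: inconsistent slice shapes {shapes}")
    vox = np.stack(slices, axis=0)
    d0 = datasets[0]
    spacing = getattr(d0, "PixelSpacing", None)
    thickness = getattr(d0, "SliceThickness", None)
    if spacing is not None and thickness is not None:
        voxel_size = (float(thickness), float(spacing[0]), float(spacing[1]))
    else:
        warnings.warn(f"{path}: DICOM series lacks spacing tags; assuming 1 mm isotropic")
        voxel_size = (1.0, 1.0, 1.0)
    return ScanVolume(voxels=vox, voxel_size=voxel_size, meta={"source": str(path)})


def write_scan(scan: ScanVolume, path) -> Path:
    """Write a scan as NIfTI (.nii/.nii.gz) or multi-page TIFF (.tif)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([scan.voxel_size[2], scan.voxel_size[1], scan.voxel_size[0], 1.0])
        img = nib.Nifti1Image(np.transpose(scan.voxels, (2, 1, 0)), affine)
        img.header.set_zooms((scan.voxel_size[2], scan.voxel_size[1], scan.voxel_size[0]))
        nib.save(img, str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(
            str(path),
            scan.voxels.astype(np.float32),
            photometric="minisblack",  # a 3-slice stack must not become RGB
            description=json.dumps({"voxel_size": list(scan.voxel_size)}),
        )
    else:
        raise ValueError(f"unsupported scan output format: {path}")
    return path


# ---------------------------------------------------------------------------
# fiducial specifications

_REQUIRED_FID_KEYS = (
    "id",
    "expected_center",
    "concentration_fraction",
    "stock_iron_mg_per_ml",
    "volume_ul",
)


def read_fiducials(path) -> list[FiducialSpec]:
    """Read fiducial specs from JSON (list of objects) or CSV.

    JSON objects carry ``expected_center`` as a [z, y, x] list; CSV files
    use columns ``center_z, center_y, center_x`` instead.  A missing
    ``search_radius`` defaults to 5 voxels; any other missing field is an
    error naming the offending record.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path}: expected a JSON list of fiducial records")
    else:
        import pandas as pd

        df = pd.read_csv(path)
        needed = {"id", "center_z", "center_y", "center_x",
                  "concentration_fraction", "stock_iron_mg_per_ml", "volume_ul"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing fiducial columns {sorted(missing)}")
        records = []
        for row in df.to_dict("records"):
            rec = dict(row)
            rec["expected_center"] = [rec.pop("center_z"), rec.pop("center_y"), rec.pop("center_x")]
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: no fiducial records — calibration impossible")
    specs = []
    for i, rec in enumerate(records):
        label = rec.get("id", f"record {i}")
        missing = [k for k in _REQUIRED_FID_KEYS if k not in rec or rec[k] is None]
        if missing:
            raise ValueError(f"{path}: fiducial {label!r} is missing fields {missing}")
        specs.append(
            FiducialSpec(
                id=str(rec["id"]),
                expected_center=tuple(float(v) for v in rec["expected_center"]),
                concentration_fraction=float(rec["concentration_fraction"]),
                stock_iron_mg_per_ml=float(rec["stock_iron_mg_per_ml"]),
                volume_ul=float(rec["volume_ul"]),
                search_radius=float(rec.get("search_radius") or DEFAULT_SEARCH_RADIUS),
            )
        )
    ids = [s.id for s in specs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate fiducial ids {sorted(dupes)}")
    return specs


def write_fiducials(specs, path) -> Path:
    path = Path(path)
    records = [
        {
            "id": s.id,
            "expected_center": list(s.expected_center),
            "concentration_fraction": s.concentration_fraction,
            "stock_iron_mg_per_ml": s.stock_iron_mg_per_ml,
            "volume_ul": s.volume_ul,
            "search_radius": s.search_radius,
        }
        for s in specs
    ]
    path.write_text(json.dumps(records, indent=2))
    return path


# ---------------------------------------------------------------------------
# reports


def write_report(result, out_dir, mask_format: str = "nifti") -> dict:
    """Write a quantification result as JSON + CSV + mask volumes.

    ``result`` is a :class:`mpiquant.quantify.QuantificationResult`.
    Files written into ``out_dir``: ``report.json`` (curve, TIVs, cluster
    diagnostics), ``slices.csv`` (per-slice table), ``roi_mask`` and
    ``graft_mask`` volumes aligned with the input.  Returns the mapping
    of file roles to paths.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = result.to_dict()
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))

    csv_path = out_dir / "slices.csv"
    pd.DataFrame(report["per_slice"]).to_csv(csv_path, index=False)

    ext = ".nii.gz" if mask_format == "nifti" else ".tif"
    paths = {"report": json_path, "slices": csv_path}
    seg = result.segmentation
    voxel_size = result.voxel_size
    for name, mask in (("roi_mask", seg.roi_mask), ("graft_mask", seg.graft_mask)):
        if mask is None:
            continue
        mpath = out_dir / f"{name}{ext}"
        write_scan(ScanVolume(mask.astype(np.uint8), voxel_size=voxel_size), mpath)
        paths[name] = mpath
    return paths
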