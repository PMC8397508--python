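"""Synthetic MPI phantom generation with known ground-truth iron content.

MPI signal is linear in tracer (iron) mass, and a point-like tracer
deposit appears in a reconstructed volume as an approximately Gaussian
blob.  The generator exploits exactly that: every iron source deposits a
Gaussian blob whose *intensity integral* equals ``signal_per_ug x
iron_ug``; noise (multiplicative, then additive, then clipping at zero)
is applied after the blur.  Nothing about scanner physics (drive field,
harmonics, x-space reconstruction) is simulated — linearity is assumed,
which is the property the downstream calibration relies on.

The default scene mimics a small-animal scanner bed: three fiducial
markers of 10/20/40% VivoTrax (5.5 mg/ml iron, 1 ul → 0.55/1.1/2.2 ug)
at fixed positions along one edge of the volume, plus one graft source,
in a 36-slice volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .scan_io import FiducialSpec, ScanVolume

__all__ = [
    "IronSource",
    "PhantomConfig",
    "GroundTruth",
    "VIVOTRAX_STOCK_MG_PER_ML",
    "DEFAULT_FIDUCIAL_FRACTIONS",
    "default_fiducials",
    "default_graft_center",
    "render_scan",
    "make_phantom_series",
    "make_longitudinal_series",
    "DEFAULT_DAY_TIVS",
]

#: Iron concentration of undiluted VivoTrax stock, mg/ml.
VIVOTRAX_STOCK_MG_PER_ML = 5.5

#: Concentration fractions of the three standard fiducial markers.
DEFAULT_FIDUCIAL_FRACTIONS = (0.10, 0.20, 0.40)

DEFAULT_FIDUCIAL_VOLUME_UL = 1.0
DEFAULT_GRID_SHAPE = (36, 64, 64)
DEFAULT_PSF_SIGMA = (1.0, 1.5, 1.5)

#: Default longitudinal ground truth (day -> ug iron): TIV rises from
#: day 1 to day 7 and falls by day 28.
DEFAULT_DAY_TIVS = {1: 4.0, 7: 5.0, 28: 2.0}


@dataclass(frozen=True)
class IronSource:
    """A point deposit of iron at a voxel position.

    ``center`` is (z, y, x) in 0-based voxel coordinates; ``iron_ug`` is
    the iron mass in micrograms; ``kind`` is ``"fiducial"`` or ``"graft"``.
    """

    center: tuple
    iron_ug: float
    kind: str = "graft"

    def __post_init__(self):
        if self.iron_ug < 0:
            raise ValueError(f"iron_ug must be >= 0, got {self.iron_ug}")
        if self.kind not in ("fiducial", "graft"):
            raise ValueError(f"kind must be 'fiducial' or 'graft', got {self.kind!r}")


@dataclass
class PhantomConfig:
    """Scene and noise description for one synthetic scan.

    Parameters
    ----------
    grid_shape : (z, y, x) voxels per axis.
    voxel_size : mm per axis.
    signal_per_ug : intensity-sum units produced per ug of iron
        (scanner gain, arbitrary units).
    psf_sigma : Gaussian point-spread width in voxels per axis
        (scalar or per-axis).
    noise_additive_sd : additive Gaussian noise SD in intensity units;
        ``None`` means 0.5% of the peak noise-free fiducial intensity.
    noise_multiplicative_cv : unitless coefficient of variation of the
        per-voxel multiplicative noise.
    rng_seed : seed for the noise generator.
    sources : iron deposits in the scene.
    """

    grid_shape: tuple = DEFAULT_GRID_SHAPE
    voxel_size: tuple = (1.0, 1.0, 1.0)
    signal_per_ug: float = 1000.0
    psf_sigma: tuple = DEFAULT_PSF_SIGMA
    noise_additive_sd: float | None = None
    noise_multiplicative_cv: float = 0.01
    rng_seed: int = 42
    sources: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes all >= 1, got {self.grid_shape}")
        if self.signal_per_ug <= 0:
            raise ValueError("signal_per_ug must be > 0")
        sig = np.broadcast_to(np.asarray(self.psf_sigma, dtype=float), (3,))
        if np.any(sig < 0):
            raise ValueError("psf_sigma must be >= 0")
        object.__setattr__(self, "psf_sigma", tuple(sig))
        if self.noise_additive_sd is not None and self.noise_additive_sd < 0:
            raise ValueError("noise_additive_sd must be >= 0")
        if self.noise_multiplicative_cv < 0:
            raise ValueError("noise_multiplicative_cv must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually put into a scan."""

    sources: list
    noise_free: np.ndarray
    total_graft_iron_ug: float
    total_fiducial_iron_ug: float
    peak_fiducial_intensity: float
    noise_additive_sd_used: float

    def to_dict(self) -> dict:
        """JSON-serialisable summary (the voxel grid is omitted)."""
        return {
            "sources": [
                {"center": list(s.center), "iron_ug": s.iron_ug, "kind": s.kind}
                for s in self.sources
            ],
            "total_graft_iron_ug": self.total_graft_iron_ug,
            "total_fiducial_iron_ug": self.total_fiducial_iron_ug,
            "peak_fiducial_intensity": self.peak_fiducial_intensity,
            "noise_additive_sd_used": self.noise_additive_sd_used,
        }


def default_fiducials(grid_shape: tuple = DEFAULT_GRID_SHAPE) -> list[FiducialSpec]:
    """The standard three-fiducial layout for a given grid.

    Markers sit along one edge of the volume (small y), each in its own
    z-slab so no slice mixes two sources, at the positions used for every
    generated scan ("same location in every scan" is what makes them
    usable as a calibration reference).
    """
    nz, ny, nx = grid_shape
    zs = [round(nz * f) for f in (0.14, 0.36, 0.58)]
    xs = [round(nx * f) for f in (0.25, 0.50, 0.75)]
    y = round(ny * 0.125)
    specs = []
    for i, (frac, z, x) in enumerate(zip(DEFAULT_FIDUCIAL_FRACTIONS, zs, xs)):
        specs.append(
            FiducialSpec(
                id=f"fid{int(round(frac * 100))}",
                expected_center=(z, y, x),
                concentration_fraction=frac,
                stock_iron_mg_per_ml=VIVOTRAX_STOCK_MG_PER_ML,
                volume_ul=DEFAULT_FIDUCIAL_VOLUME_UL,
                search_radius=5.0,
            )
        )
    return specs


def default_graft_center(grid_shape: tuple = DEFAULT_GRID_SHAPE) -> tuple:
    """Graft position: its own z-slab, centred in-plane, clear of the fiducial edge."""
    nz, ny, nx = grid_shape
    return (round(nz * 0.8), round(ny * 0.625), round(nx * 0.5))


def fiducial_sources(specs: Sequence[FiducialSpec]) -> list[IronSource]:
    """IronSources for a list of fiducial specs (mg/ml x ul = ug)."""
    return [
        IronSource(
            center=tuple(s.expected_center),
            iron_ug=s.concentration_fraction * s.stock_iron_mg_per_ml * s.volume_ul,
            kind="fiducial",
        )
        for s in specs
    ]


def _render_field(shape, sources, signal_per_ug, sigma) -> np.ndarray:
    """Noise-free intensity field: delta deposits blurred by the PSF.

    The discrete Gaussian kernel is normalised, so the voxel sum of a
    fully interior blob equals signal_per_ug x iron_ug exactly; blobs
    near the boundary lose the truncated part of their kernel.
    """
    field_ = np.zeros(shape, dtype=float)
    for i, src in enumerate(sources):
        c = tuple(int(v) for v in src.center)
        if any(not (0 <= c[a] < shape[a]) for a in range(3)):
            raise ValueError(
                f"source {i} ({src.kind}, iron {src.iron_ug} ug) at {src.center} "
                f"lies outside the grid {shape}"
            )
        field_[c] += signal_per_ug * src.iron_ug
    if any(s > 0 for s in sigma):
        field_ = ndimage.gaussian_filter(field_, sigma=sigma, mode="constant", truncate=4.0)
    return field_


def render_scan(config: PhantomConfig, meta: dict | None = None):
    """Render one synthetic scan.

    Returns ``(ScanVolume, GroundTruth)``.  Identical config (including
    ``rng_seed``) produces a byte-identical volume.
    """
    fids = [s for s in config.sources if s.kind == "fiducial"]
    grafts = [s for s in config.sources if s.kind == "graft"]
    fid_field = _render_field(config.grid_shape, fids, config.signal_per_ug, config.psf_sigma)
    graft_field = _render_field(config.grid_shape, grafts, config.signal_per_ug, config.psf_sigma)
    noise_free = fid_field + graft_field

    peak_fid = float(fid_field.max()) if fids else 0.0
    if config.noise_additive_sd is None:
        # default noise scale: 0.5% of the brightest fiducial voxel (or of
        # the brightest voxel overall when the scene has no fiducials)
        ref = peak_fid if fids else float(noise_free.max())
        add_sd = 0.005 * ref
    else:
        add_sd = float(config.noise_additive_sd)

    rng = np.random.default_rng(config.rng_seed)
    vox = noise_free.copy()
    if config.noise_multiplicative_cv > 0:
        vox = vox * (1.0 + config.noise_multiplicative_cv * rng.standard_normal(vox.shape))
    if add_sd > 0:
        vox = vox + add_sd * rng.standard_normal(vox.shape)
    np.clip(vox, 0.0, None, out=vox)

    scan = ScanVolume(voxels=vox, voxel_size=tuple(config.voxel_size), meta=dict(meta or {}))
    scan.meta.setdefault("modality", "MPI")
    truth = GroundTruth(
        sources=list(config.sources),
        noise_free=noise_free,
        total_graft_iron_ug=float(sum(s.iron_ug for s in grafts)),
        total_fiducial_iron_ug=float(sum(s.iron_ug for s in fids)),
        peak_fiducial_intensity=peak_fid,
        noise_additive_sd_used=add_sd,
    )
    return scan, truth


def make_phantom_series(
    counts: Sequence[int],
    iron_per_organoid_ug: float = 0.01,
    config: PhantomConfig | None = None,
    fiducials: Sequence[FiducialSpec] | None = None,
):
    """The dilution-series experiment: one scan per organoid count.

    Each scan contains the standard three fiducials plus a single graft
    source of ``count x iron_per_organoid_ug`` micrograms (count 0 gives a
    graft-free scan).  Scan ``i`` uses seed ``config.rng_seed + i``.

    Returns a list of ``(ScanVolume, GroundTruth)`` pairs.
    """
    if iron_per_organoid_ug < 0:
        raise ValueError("iron_per_organoid_ug must be >= 0")
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError(f"organoid counts must be >= 0, got {counts}")
    base = config or PhantomConfig()
    fids = fiducial_sources(fiducials if fiducials is not None else default_fiducials(base.grid_shape))
    graft_at = default_graft_center(base.grid_shape)
    out = []
    for i, count in enumerate(counts):
        sources = list(fids)
        iron = count * iron_per_organoid_ug
        if iron > 0:
            sources.append(IronSource(center=graft_at, iron_ug=iron, kind="graft"))
        cfg = replace(base, sources=sources, rng_seed=base.rng_seed + i)
        scan, truth = render_scan(cfg, meta={"subject_id": f"phantom-{count}", "organoid_count": count})
        out.append((scan, truth))
    return out


def make_longitudinal_series(
    day_tivs: Mapping[int, float] | None = None,
    config: PhantomConfig | None = None,
    fiducials: Sequence[FiducialSpec] | None = None,
):
    """One scan per imaging day with prescribed ground-truth graft iron.

    The default trajectory follows the biology seen in graft monitoring:
    TIV increases from day 1 to day 7 (tracer aggregation / graft
    remodelling) and decreases by day 28 (iron clearance).

    Returns ``[(day, ScanVolume, GroundTruth), ...]`` ordered by day.
    """
    day_tivs = dict(DEFAULT_DAY_TIVS if day_tivs is None else day_tivs)
    if len(day_tivs) == 0:
        raise ValueError("day_tivs must contain at least one day")
    if any(v < 0 for v in day_tivs.values()):
        raise ValueError("TIV values must be >= 0")
    base = config or PhantomConfig()
    fids = fiducial_sources(fiducials if fiducials is not None else default_fiducials(base.grid_shape))
    graft_at = default_graft_center(base.grid_shape)
    out = []
    for i, day in enumerate(sorted(day_tivs)):
        iron = float(day_tivs[day])
        sources = list(fids)
        if iron > 0:
            sources.append(IronSource(center=graft_at, iron_ug=iron, kind="graft"))
        cfg = replace(base, sources=sources, rng_seed=base.rng_seed + 101 * (i + 1))
        scan, truth = render_scan(cfg, meta={"subject_id": f"day-{day}", "timepoint": day})
        out.append((day, scan, truth))
    return out
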