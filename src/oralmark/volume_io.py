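"""Data model and I/O for endoscopic OCT volumes.

An endoscopic rotary-pullback catheter produces a cylindrical intensity
volume indexed (frame θ, pullback y, depth z).  Volumes are stored on disk
as multi-page 32-bit float TIFF (one page per longitudinal frame, rows = z,
columns = y) with a JSON metadata sidecar ``<name>.meta.json``.  Intensity
is calibrated dB by default; a sidecar flag ``scale: linear`` converts
linear power to dB on load.

Axial sample spacing is optical path length; physical depth uses the
refractive index of the immersion medium (water, n = 1.333, by default).
The analysis pipeline operates on volumes resampled to 10 µm square pixels
in (y, z) with bicubic interpolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: Edge length of the isotropic analysis pixel, µm.
ISO_PIXEL_UM = 10.0

#: Relative tolerance under which a spacing counts as already isotropic.
_SPACING_RTOL = 1e-3

_REQUIRED_META = (
    "y_spacing_um",
    "z_spacing_optical_um",
    "n_medium",
    "frames_per_rev",
)
_OPTIONAL_META = ("pullback_speed_mm_s", "rotation_hz", "scale")


class VolumeLoadError(RuntimeError):
    """Raised when a volume or its metadata sidecar fails validation."""


@dataclass
class OctVolume:
    """A calibrated OCT intensity volume plus acquisition metadata.

    Parameters
    ----------
    intensity_db
        3-D array, shape (F frames, Y pullback samples, Z depth samples),
        intensity in dB.  Stored as float32.
    y_spacing_um
        Pullback sample spacing, µm.
    z_spacing_optical_um
        Axial optical-path sample spacing, µm.
    n_medium
        Refractive index of the immersion medium (water by default).
    frames_per_rev
        Number of longitudinal frames in the volume.
    pullback_speed_mm_s, rotation_hz
        Acquisition kinematics; carried through, not used in analysis.
    """

    intensity_db: np.ndarray
    y_spacing_um: float
    z_spacing_optical_um: float
    n_medium: float = 1.333
    frames_per_rev: int = 512
    pullback_speed_mm_s: float = 1.0
    rotation_hz: float = 100.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity_db, dtype=np.float32)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("intensity_db must be a non-empty (F, Y, Z) array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity_db contains non-finite values")
        if self.y_spacing_um <= 0 or self.z_spacing_optical_um <= 0:
            raise ValueError("sample spacings must be positive")
        if self.n_medium < 1:
            raise ValueError("n_medium must be >= 1")
        self.intensity_db = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity_db.shape

    @property
    def n_frames(self) -> int:
        return self.intensity_db.shape[0]

    @property
    def z_spacing_physical_um(self) -> float:
        """Axial spacing in physical depth (optical path / n_medium), µm."""
        return self.z_spacing_optical_um / self.n_medium

    def metadata(self) -> dict:
        meta = dataclasses.asdict(self)
        del meta["intensity_db"]
        meta["scale"] = "db"
        return meta


@dataclass
class EnFaceMap:
    """A 2-D top-down (frame × pullback) reduction of a volume.

    ``values`` has shape (F, Y); missing entries are NaN.  ``units`` is a
    free-text label (e.g. "um", "mm^-1", "a.u.").
    """

    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("en face map must be 2-D (F, Y)")
        self.values = arr


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def save_volume(volume: OctVolume, path: str | Path) -> Path:
    """Write a volume as multi-page float32 TIFF plus JSON sidecar.

    Pages are written rows = z, columns = y.  Returns the sidecar path.
    """
    path = Path(path)
    pages = np.transpose(volume.intensity_db, (0, 2, 1))  # (F, Z, Y)
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(volume.metadata(), indent=1))
    return sidecar


def load_volume(path: str | Path) -> OctVolume:
    """Load a multi-page TIFF volume with its JSON metadata sidecar.

    Raises :class:`VolumeLoadError` on a missing sidecar, missing metadata
    fields, a frame-count mismatch between sidecar and TIFF, or non-finite
    pixels.  Sidecar ``scale: linear`` inputs are converted to dB.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeLoadError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise VolumeLoadError(f"sidecar {sidecar} missing fields: {missing}")

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise VolumeLoadError(f"expected a multi-page 2-D TIFF, got shape {pages.shape}")
    if int(meta["frames_per_rev"]) != pages.shape[0]:
        raise VolumeLoadError(
            f"sidecar declares {meta['frames_per_rev']} frames but TIFF has "
            f"{pages.shape[0]} pages"
        )
    intensity = np.transpose(pages, (0, 2, 1))  # (F, Y, Z)
    if not np.all(np.isfinite(intensity)):
        raise VolumeLoadError("volume contains non-finite pixels")
    if meta.get("scale", "db") == "linear":
        if np.any(intensity <= 0):
            raise VolumeLoadError("linear-scale volume has non-positive pixels")
        intensity = 10.0 * np.log10(intensity)

    kwargs = {k: meta[k] for k in _REQUIRED_META}
    for k in ("pullback_speed_mm_s", "rotation_hz"):
        if k in meta:
            kwargs[k] = meta[k]
    try:
        return OctVolume(intensity_db=intensity, **kwargs)
    except ValueError as exc:  # pragma: no cover - re-tagged for callers
        raise VolumeLoadError(str(exc)) from exc


def rescale_isotropic(volume: OctVolume, target_um: float = ISO_PIXEL_UM) -> OctVolume:
    """Resample each frame to square ``target_um`` pixels in (y, z).

    Physical axial spacing is ``z_spacing_optical_um / n_medium``; both axes
    are resampled with separable bicubic (not-a-knot cubic spline)
    interpolation.  Frame count is unchanged.  If both spacings already
    equal the target (to within a small relative tolerance) the volume is
    returned unchanged.
    """
    from scipy.interpolate import CubicSpline

    z_phys = volume.z_spacing_physical_um
    y_ok = abs(volume.y_spacing_um - target_um) <= _SPACING_RTOL * target_um
    z_ok = abs(z_phys - target_um) <= _SPACING_RTOL * target_um
    if y_ok and z_ok:
        return volume

    F, Y, Z = volume.shape
    n_y = int(np.floor((Y - 1) * volume.y_spacing_um / target_um)) + 1 if not y_ok else Y
    n_z = int(np.floor((Z - 1) * z_phys / target_um)) + 1 if not z_ok else Z
    yi = np.arange(n_y) * (target_um / volume.y_spacing_um) if not y_ok else np.arange(Y, dtype=float)
    zi = np.arange(n_z) * (target_um / z_phys) if not z_ok else np.arange(Z, dtype=float)

    out = np.empty((F, n_y, n_z), dtype=np.float32)
    for f in range(F):
        frame = volume.intensity_db[f].astype(np.float64)
        if not z_ok:
            frame = CubicSpline(np.arange(Z), frame, axis=1)(zi)
        if not y_ok:
            frame = CubicSpline(np.arange(Y), frame, axis=0)(yi)
        out[f] = frame
    return OctVolume(
        intensity_db=out,
        y_spacing_um=target_um,
        z_spacing_optical_um=target_um * volume.n_medium,
        n_medium=volume.n_medium,
        frames_per_rev=volume.frames_per_rev,
        pullback_speed_mm_s=volume.pullback_speed_mm_s,
        rotation_hz=volume.rotation_hz,
    )


def mean_enface(
    grid: np.ndarray, region: np.ndarray | None = None, units: str = ""
) -> EnFaceMap:
    """Mean over depth of each A-line, optionally restricted to a region.

    ``grid`` is (F, Y, Z); ``region`` a boolean mask of the same shape.
    Entries with no included pixel are NaN.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if region is None:
        return EnFaceMap(grid.mean(axis=2), units=units)
    region = np.asarray(region, dtype=bool)
    if region.shape != grid.shape:
        raise ValueError("region mask shape must match the grid")
    count = region.sum(axis=2)
    total = np.where(region, grid, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return EnFaceMap(values, units=units)


def save_enface(emap: EnFaceMap, path: str | Path) -> None:
    """Write an en face map as float32 TIFF plus a CSV alongside."""
    path = Path(path)
    tifffile.imwrite(path, emap.values.astype(np.float32), photometric="minisblack")
    np.savetxt(path.with_suffix(".csv"), emap.values, delimiter=",", fmt="%.6g")


def load_enface(path: str | Path, units: str = "") -> EnFaceMap:
    return EnFaceMap(tifffile.imread(Path(path)).astype(np.float64), units=units)
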