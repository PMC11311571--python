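"""Per-frame tissue region masks from layer-surface segmentations.

Segmentation supplies, per A-line, the depth index of the epithelium top
and (where resolvable) of the epithelial-stromal boundary.  This module
turns those curves into boolean region masks:

* epithelium E = [top, boundary), stroma S = [boundary, bottom);
* where the boundary is not resolvable, the entire visualized depth is
  treated as epithelium (E = [top, bottom), S empty) and the A-line is
  flagged as loss-of-boundary — itself a biomarker downstream;
* the epithelium is split into upper (UE) and lower (LE) halves, the odd
  pixel going to UE;
* the visualized region ends where the signal falls to within 6 dB of the
  noise floor (sustained over k consecutive pixels), capped to stay clear
  of the bottom rows used for noise-floor estimation.

En face bookkeeping (tissue contact, artifacts, lesion area) and the
azimuthal edge erosion that retains only the central 50% of each contact
run also live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

#: Number of bottom rows (10 µm pixels → 250 µm) used for the noise floor.
NOISE_FLOOR_ROWS = 25

#: Signal must exceed the noise floor by this margin to count as visualized.
VISUALIZED_MARGIN_DB = 6.0

#: Consecutive sub-threshold pixels that constitute a sustained drop.
SUSTAINED_DROP_PX = 3

_GAUSS_SIGMA = 1.0  # 5-pixel (±2) Gaussian support
_GAUSS_TRUNCATE = 2.0


@dataclass
class SurfaceSet:
    """Per-(frame, pullback) layer-surface depth indices; NaN = missing.

    ``epi_top`` is the epithelium top surface, ``boundary`` the
    epithelial-stromal boundary.  Where both are present the boundary must
    lie strictly below the top.
    """

    epi_top: np.ndarray
    boundary: np.ndarray

    def __post_init__(self) -> None:
        self.epi_top = np.asarray(self.epi_top, dtype=np.float64)
        self.boundary = np.asarray(self.boundary, dtype=np.float64)
        if self.epi_top.shape != self.boundary.shape or self.epi_top.ndim != 2:
            raise ValueError("surface arrays must share a 2-D (F, Y) shape")
        both = np.isfinite(self.epi_top) & np.isfinite(self.boundary)
        if np.any(self.boundary[both] <= self.epi_top[both]):
            raise ValueError("boundary must lie strictly below the epithelium top")

    @property
    def shape(self) -> tuple[int, int]:
        return self.epi_top.shape

    def tissue(self) -> np.ndarray:
        """A-lines containing tissue (an epithelium surface was found)."""
        return np.isfinite(self.epi_top)

    def to_json(self, path: str | Path) -> None:
        def pack(a: np.ndarray) -> list:
            return [[None if not np.isfinite(v) else int(v) for v in row] for row in a]

        Path(path).write_text(
            json.dumps({"epi_top": pack(self.epi_top), "boundary": pack(self.boundary)})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SurfaceSet":
        raw = json.loads(Path(path).read_text())

        def unpack(rows: list) -> np.ndarray:
            return np.array(
                [[np.nan if v is None else float(v) for v in row] for row in rows]
            )

        return cls(unpack(raw["epi_top"]), unpack(raw["boundary"]))


@dataclass
class EnFaceMaskSet:
    """En face annotation masks: tissue contact, artifacts, lesion area."""

    contact: np.ndarray
    artifact: np.ndarray
    lesion: np.ndarray

    def __post_init__(self) -> None:
        self.contact = np.asarray(self.contact, dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        self.lesion = np.asarray(self.lesion, dtype=bool)
        if not (self.contact.shape == self.artifact.shape == self.lesion.shape):
            raise ValueError("mask shapes must agree")
        if self.contact.ndim != 2:
            raise ValueError("masks must be 2-D (F, Y)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.contact.shape

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("contact", "artifact", "lesion"):
            arr = (getattr(self, name).astype(np.uint8)) * 255
            iio.imwrite(directory / f"{name}.png", arr)

    @classmethod
    def load(cls, directory: str | Path) -> "EnFaceMaskSet":
        directory = Path(directory)
        masks = {}
        for name in ("contact", "artifact", "lesion"):
            masks[name] = np.asarray(iio.imread(directory / f"{name}.png")) > 0
        return cls(**masks)


@dataclass
class RegionMasks:
    """Boolean tissue-region masks, shape (F, Y, Z), plus per-A-line flags."""

    epithelium: np.ndarray
    stroma: np.ndarray
    upper_epi: np.ndarray
    lower_epi: np.ndarray
    visualized: np.ndarray
    loss_flag: np.ndarray  # (F, Y): boundary unresolved on a tissue A-line
    tissue: np.ndarray  # (F, Y): epithelium surface present


def smooth_frame(frame_db: np.ndarray) -> np.ndarray:
    """5-pixel (σ = 1, ±2 support) 2-D Gaussian smoothing, reflective borders."""
    return ndimage.gaussian_filter(
        np.asarray(frame_db, dtype=np.float64),
        sigma=_GAUSS_SIGMA,
        truncate=_GAUSS_TRUNCATE,
        mode="reflect",
    )


def noise_floor(
    frame_db: np.ndarray,
    epi_top: np.ndarray,
    window: int = NOISE_FLOOR_ROWS,
) -> float:
    """Noise floor of one frame, dB.

    The bottom ``window`` depth rows (250 µm at 10 µm pixels) are taken,
    restricted to A-lines that contain tissue (an epithelium surface),
    Gaussian-smoothed (5-pixel kernel), and averaged.

    ``frame_db`` is (Y, Z); ``epi_top`` is the (Y,) surface row with NaN
    where no tissue was found.
    """
    frame_db = np.asarray(frame_db, dtype=np.float64)
    included = np.isfinite(np.asarray(epi_top, dtype=np.float64))
    if not included.any():
        raise ValueError("no A-line in the frame contains an epithelium surface")
    block = frame_db[included, -window:]
    return float(smooth_frame(block).mean())


def visualized_bottom(
    profile_db: np.ndarray,
    floor_db: float,
    epi_top: int,
    k: int = SUSTAINED_DROP_PX,
    margin: int = NOISE_FLOOR_ROWS,
    threshold_db: float = VISUALIZED_MARGIN_DB,
) -> int:
    """Bottom index of the visualized region on one (smoothed) A-line.

    Scans down from ``epi_top`` for the first run of ``k`` consecutive
    pixels below ``floor_db + threshold_db``; the visualized region is
    [epi_top, b) where b is the start of that run, capped at Z - margin so
    it stays disjoint from the noise-floor window.  Returns ``epi_top``
    (an empty region) when the profile is already sub-threshold there.
    """
    profile_db = np.asarray(profile_db, dtype=np.float64)
    z = profile_db.size
    cap = z - margin
    if not 0 <= epi_top < z:
        raise ValueError("epi_top outside the profile")
    if epi_top >= cap:
        return epi_top
    below = profile_db[epi_top:cap] < floor_db + threshold_db
    n = below.size
    run = 0
    for i in range(n):
        run = run + 1 if below[i] else 0
        if run == k:
            return epi_top + i - k + 1
    return cap


def visualized_bottom_map(
    smoothed_db: np.ndarray,
    floors_db: np.ndarray,
    surfaces: SurfaceSet,
    k: int = SUSTAINED_DROP_PX,
    margin: int = NOISE_FLOOR_ROWS,
    threshold_db: float = VISUALIZED_MARGIN_DB,
) -> np.ndarray:
    """Vectorized :func:`visualized_bottom` over a (F, Y, Z) smoothed volume.

    ``floors_db`` is per-frame (F,).  Returns a float (F, Y) array of bottom
    indices, NaN on A-lines without tissue.
    """
    smoothed_db = np.asarray(smoothed_db, dtype=np.float64)
    F, Y, Z = smoothed_db.shape
    cap = Z - margin
    thr = np.asarray(floors_db, dtype=np.float64)[:, None, None] + threshold_db
    below = smoothed_db < thr

    # start of a k-long sub-threshold run at each depth
    run_start = np.ones((F, Y, Z), dtype=bool)
    for off in range(k):
        idx_max = Z - k + 1
        run_start[:, :, :idx_max] &= below[:, :, off : off + idx_max]
    run_start[:, :, Z - k + 1 :] = False

    top = surfaces.epi_top
    tissue = np.isfinite(top)
    zidx = np.arange(Z)[None, None, :]
    top_i = np.where(tissue, top, 0).astype(int)[:, :, None]
    # the k-long run must complete above the cap, as in the scalar scan
    candidate = run_start & (zidx >= top_i) & (zidx <= cap - k)

    has_drop = candidate.any(axis=2)
    first = np.argmax(candidate, axis=2)
    bottom = np.where(has_drop, first, cap).astype(np.float64)
    bottom = np.minimum(bottom, cap)
    # a surface at/below the cap leaves an empty visualized region
    bottom = np.maximum(bottom, np.where(tissue, top, 0))
    bottom[~tissue] = np.nan
    return bottom


def build_region_masks(
    surfaces: SurfaceSet, bottoms: np.ndarray, n_depth: int
) -> RegionMasks:
    """Assemble E/S/UE/LE/visualized masks from surfaces and bottom indices.

    Where the boundary is present, E = [top, boundary) and
    S = [boundary, bottom); where it is missing, the entire visualized
    region is epithelium and the A-line is flagged as loss-of-boundary.
    UE takes the upper ⌈|E|/2⌉ pixels of E, LE the remainder.
    """
    top = surfaces.epi_top
    bnd = surfaces.boundary
    bottoms = np.asarray(bottoms, dtype=np.float64)
    tissue = np.isfinite(top) & np.isfinite(bottoms)
    loss = tissue & ~np.isfinite(bnd)

    top_i = np.where(tissue, top, 0).astype(int)
    bot_i = np.where(tissue, bottoms, 0).astype(int)
    if np.any(bot_i[tissue] < top_i[tissue]):
        raise ValueError("visualized bottom above the epithelium top")
    # epithelium end: boundary where present (clipped to bottom), else bottom
    e_end = np.where(loss | ~tissue, bot_i, np.minimum(np.where(np.isfinite(bnd), bnd, 0), bot_i)).astype(int)

    z = np.arange(n_depth)[None, None, :]
    t = top_i[:, :, None]
    e = e_end[:, :, None]
    b = bot_i[:, :, None]
    live = tissue[:, :, None]

    epithelium = live & (z >= t) & (z < e)
    stroma = live & (z >= e) & (z < b)
    visualized = live & (z >= t) & (z < b)

    e_len = e_end - top_i
    ue_len = (e_len + 1) // 2  # odd pixel goes to the upper half
    ue_end = (top_i + ue_len)[:, :, None]
    upper_epi = epithelium & (z < ue_end)
    lower_epi = epithelium & (z >= ue_end)

    return RegionMasks(
        epithelium=epithelium,
        stroma=stroma,
        upper_epi=upper_epi,
        lower_epi=lower_epi,
        visualized=visualized,
        loss_flag=loss,
        tissue=tissue,
    )


def erode_central(contact: np.ndarray) -> np.ndarray:
    """Azimuthal erosion: keep the central 50% of each contact run.

    For each pullback column, every maximal run of ``L`` contiguous contact
    frames is replaced by its central ``⌊L/2⌋`` frames (at least one frame
    is retained).  Mitigates edge effects where the probe grazes tissue
    tangentially at the limits of the azimuthal scan.
    """
    contact = np.asarray(contact, dtype=bool)
    out = np.zeros_like(contact)
    F, Y = contact.shape
    for y in range(Y):
        col = contact[:, y]
        f = 0
        while f < F:
            if not col[f]:
                f += 1
                continue
            start = f
            while f < F and col[f]:
                f += 1
            length = f - start
            keep = max(length // 2, 1)
            offset = (length - keep) // 2
            out[start + offset : start + offset + keep, y] = True
    return out
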