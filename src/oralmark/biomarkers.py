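"""The seven quantitative biomarkers and per-volume summaries.

Morphology:
    * epithelial depth (µm) — height of the epithelium mask per A-line;
    * loss of epithelial-stromal boundary (%) — fraction of tissue A-lines
      where no boundary was resolvable, excluding artifacts (one value per
      volume).

Attenuation (mm^-1): mean en face projections of the depth-resolved
attenuation coefficient over the whole visualized depth ("overall"), the
epithelium, and the stroma.

Stratification (a.u., range [-1, 1]): ratiometric contrast
(μ_a - μ_b) / (μ_a + μ_b) between per-A-line mean attenuation of two
regions — epithelium vs stroma, and upper vs lower epithelium halves.

For statistics each volume is reduced to a single median per biomarker,
taken over the azimuthally eroded tissue-contact mask with artifacts
excluded (and restricted to the labelled lesion area for lesion volumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import attenuation as att_mod
from . import regions as reg_mod
from .regions import EnFaceMaskSet, RegionMasks, SurfaceSet
from .volume_io import ISO_PIXEL_UM, EnFaceMap, OctVolume

BIOMARKER_NAMES = (
    "depth_um",
    "loss_pct",
    "mu_overall",
    "mu_epi",
    "mu_stroma",
    "es_strat",
    "ie_strat",
)

BIOMARKER_UNITS = {
    "depth_um": "um",
    "loss_pct": "%",
    "mu_overall": "mm^-1",
    "mu_epi": "mm^-1",
    "mu_stroma": "mm^-1",
    "es_strat": "a.u.",
    "ie_strat": "a.u.",
}


@dataclass
class BiomarkerMaps:
    """En face maps / scalars for the seven biomarkers of one volume."""

    depth_um: EnFaceMap
    mu_overall: EnFaceMap
    mu_epi: EnFaceMap
    mu_stroma: EnFaceMap
    es_strat: EnFaceMap
    ie_strat: EnFaceMap
    loss_pct: float
    loss_mask: np.ndarray

    def map_items(self) -> list[tuple[str, EnFaceMap]]:
        return [
            (name, getattr(self, name))
            for name in BIOMARKER_NAMES
            if name != "loss_pct"
        ]


@dataclass
class VolumeSummary:
    """One median per biomarker plus retained-A-line counts for one volume."""

    medians: dict[str, float]
    counts: dict[str, int]
    role: str = "lesion"


def epithelial_depth_map(masks: RegionMasks, pixel_um: float = ISO_PIXEL_UM) -> EnFaceMap:
    """Epithelium height per A-line, µm (|E| pixels x pixel size).

    On loss-of-boundary A-lines the epithelium spans the full visualized
    depth; A-lines without tissue are missing.
    """
    count = masks.epithelium.sum(axis=2).astype(np.float64)
    values = np.where(masks.tissue, count * pixel_um, np.nan)
    return EnFaceMap(values, units="um")


def loss_of_boundary_pct(masks: RegionMasks, enface: EnFaceMaskSet) -> float:
    """Percent of artifact-free tissue A-lines with an unresolved boundary."""
    keep = masks.tissue & ~enface.artifact
    denom = int(keep.sum())
    if denom == 0:
        raise ValueError("no artifact-free tissue A-lines in the volume")
    return 100.0 * float((masks.loss_flag & keep).sum()) / denom


def stratification(a, b):
    """Ratiometric stratification (a - b) / (a + b), elementwise.

    Inputs are non-negative attenuation coefficients; the result lies in
    [-1, 1] and is NaN where either input is missing or both are zero.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / (a + b)
    if out.ndim == 0:
        return float(out) if np.isfinite(out) else float("nan")
    out[~np.isfinite(out)] = np.nan
    return out


@dataclass
class PipelineConfig:
    """Tunable parameters of the biomarker pipeline (defaults documented
    in the methods note)."""

    tail_px: int = att_mod.TAIL_FIT_PX
    lateral_avg: int = att_mod.LATERAL_AVG_PX
    method: str = "log"
    sustained_drop_px: int = reg_mod.SUSTAINED_DROP_PX


def compute_all(
    volume: OctVolume,
    surfaces: SurfaceSet,
    enface: EnFaceMaskSet,
    config: PipelineConfig | None = None,
) -> BiomarkerMaps:
    """Run the full biomarker pipeline on one rescaled volume.

    Orchestrates noise-floor estimation, the 6 dB visualized-depth rule,
    region-mask construction, depth-resolved attenuation, and the seven
    features.  All maps are missing outside tissue contact and at artifact
    A-lines.
    """
    config = config or PipelineConfig()
    if abs(volume.z_spacing_physical_um - ISO_PIXEL_UM) > 0.1 or (
        abs(volume.y_spacing_um - ISO_PIXEL_UM) > 0.1
    ):
        raise ValueError("volume must be rescaled to 10 um isotropic pixels first")
    F, Y, Z = volume.shape
    if surfaces.shape != (F, Y) or enface.shape != (F, Y):
        raise ValueError("surfaces/masks are not aligned with the volume")

    intensity = volume.intensity_db.astype(np.float64)
    floors = np.empty(F)
    smoothed = np.empty_like(intensity)
    for f in range(F):
        smoothed[f] = reg_mod.smooth_frame(intensity[f])
        if np.isfinite(surfaces.epi_top[f]).any():
            floors[f] = reg_mod.noise_floor(intensity[f], surfaces.epi_top[f])
        else:
            floors[f] = np.nan

    ok_frames = np.isfinite(floors)
    floors_filled = np.where(ok_frames, floors, 0.0)
    bottoms = reg_mod.visualized_bottom_map(
        smoothed, floors_filled, surfaces, k=config.sustained_drop_px
    )
    masks = reg_mod.build_region_masks(surfaces, bottoms, Z)

    att = att_mod.attenuation_volume(
        volume,
        masks,
        floors_filled,
        tail_px=config.tail_px,
        lateral_avg=config.lateral_avg,
        method=config.method,
    )
    mu_overall = att_mod.region_mean_mu(att, masks, "overall")
    mu_epi = att_mod.region_mean_mu(att, masks, "epithelium")
    mu_stroma = att_mod.region_mean_mu(att, masks, "stroma")
    mu_ue = att_mod.region_mean_mu(att, masks, "upper_epithelium")
    mu_le = att_mod.region_mean_mu(att, masks, "lower_epithelium")

    depth = epithelial_depth_map(masks)
    es = EnFaceMap(stratification(mu_epi.values, mu_stroma.values), units="a.u.")
    ie = EnFaceMap(stratification(mu_ue.values, mu_le.values), units="a.u.")
    loss_pct = loss_of_boundary_pct(masks, enface)

    hide = ~enface.contact | enface.artifact
    for emap in (depth, mu_overall, mu_epi, mu_stroma, es, ie):
        emap.values[hide] = np.nan

    return BiomarkerMaps(
        depth_um=depth,
        mu_overall=mu_overall,
        mu_epi=mu_epi,
        mu_stroma=mu_stroma,
        es_strat=es,
        ie_strat=ie,
        loss_pct=loss_pct,
        loss_mask=masks.loss_flag & enface.contact & ~enface.artifact,
    )


def volume_summary(
    maps: BiomarkerMaps,
    enface: EnFaceMaskSet,
    restrict_to_lesion: bool = False,
    role: str = "lesion",
) -> VolumeSummary:
    """Reduce biomarker maps to a single median per biomarker.

    Retains A-lines in the azimuthally eroded contact mask (central 50% of
    each contact run), excludes artifacts, and — when
    ``restrict_to_lesion`` — keeps only the labelled lesion area.  Missing
    entries are skipped; the loss-of-boundary percentage is passed through
    unchanged.
    """
    retained = reg_mod.erode_central(enface.contact) & ~enface.artifact
    if restrict_to_lesion:
        retained &= enface.lesion
    if not retained.any():
        raise ValueError("no A-lines retained after masking")

    medians: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name, emap in maps.map_items():
        vals = emap.values[retained]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no defined {name} entries among retained A-lines")
        medians[name] = float(np.median(vals))
        counts[name] = int(vals.size)
    medians["loss_pct"] = maps.loss_pct
    counts["loss_pct"] = int((reg_mod.erode_central(enface.contact) & ~enface.artifact).sum())
    return VolumeSummary(medians=medians, counts=counts, role=role)
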