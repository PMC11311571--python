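"""Synthetic two-layer oral-mucosa OCT phantoms with ground truth.

The phantom emulates the appearance of lateral/ventral tongue in
endoscopic OCT: a darker epithelium over a brighter stroma, each with its
own backscatter amplitude and attenuation coefficient.  Linear power
follows the standard single-scattering round-trip decay

    P(z) = B_layer * exp(-2 * integral of mu dz)

with fully developed speckle modelled as multiplicative unit-mean
exponential noise in intensity, a deterministic additive noise floor in
linear power, and dB conversion last.  The generator also emulates the
failure modes the analysis pipeline must handle:

* loss-of-boundary regions, where the stromal backscatter step is
  suppressed and epithelium-like decay continues to the floor (no
  resolvable epithelial-stromal boundary);
* bubble artifacts, carved as strongly shadowed vertical stripes;
* contact loss at the azimuthal edges of the scan, with a linear dB
  roll-off taper at the ends of each contact run ("edge effects").

Ground truth (surfaces, en face masks, per-A-line biomarker values) is
returned alongside the volume so every downstream stage can be tested
without clinical data.  Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .regions import EnFaceMaskSet, SurfaceSet
from .volume_io import OctVolume

_PRESETS = ("contralateral", "observation_lesion", "intervention_lesion")


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic two-layer mucosa volume.

    Scalar fields (``epi_depth_um``, ``mu_epi_mm``, ``mu_stroma_mm``,
    ``surface_z_um``) may be given as constants or (F, Y) arrays.  Depths
    are physical µm on a 10 µm grid; attenuation coefficients are round-trip
    mm^-1; backscatter amplitudes are relative linear power (stroma brighter
    than epithelium).
    """

    n_frames: int = 64
    n_pullback: int = 512
    n_depth: int = 220
    y_spacing_um: float = 10.0
    z_spacing_um: float = 10.0
    n_medium: float = 1.333
    epi_depth_um: float | np.ndarray = 160.0
    mu_epi_mm: float | np.ndarray = 1.20
    mu_stroma_mm: float | np.ndarray = 3.97
    backscatter_epi: float | None = None
    backscatter_stroma: float = 1.0
    surface_z_um: float | np.ndarray = 50.0
    noise_floor_db: float | None = -50.0
    speckle: bool = True
    loss_mask: np.ndarray | None = None
    bubble_mask: np.ndarray | None = None
    contact_mask: np.ndarray | None = None
    lesion_mask: np.ndarray | None = None
    edge_taper_frames: int = 6
    edge_taper_db: float = 20.0
    bubble_shadow_db: float = 30.0
    seed: int = 0

    @property
    def enface_shape(self) -> tuple[int, int]:
        return (self.n_frames, self.n_pullback)

    def _field(self, value: float | np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=np.float64), self.enface_shape)

    def _mask(self, mask: np.ndarray | None, default: bool) -> np.ndarray:
        if mask is None:
            return np.full(self.enface_shape, default, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.enface_shape:
            raise ValueError("en face mask shape must match the grid")
        return mask

    def validate(self) -> None:
        if min(self.n_frames, self.n_pullback, self.n_depth) < 1:
            raise ValueError("grid dimensions must be positive")
        if np.any(self._field(self.epi_depth_um) < 0):
            raise ValueError("epithelial depth must be non-negative")
        if np.any(self._field(self.mu_epi_mm) < 0) or np.any(
            self._field(self.mu_stroma_mm) < 0
        ):
            raise ValueError("attenuation fields must be non-negative")
        if not self._mask(self.contact_mask, True).any():
            raise ValueError("contact map must be non-empty")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a generated phantom volume."""

    surfaces: SurfaceSet
    masks: EnFaceMaskSet
    depth_um: np.ndarray
    mu_epi: np.ndarray
    mu_stroma: np.ndarray
    loss: np.ndarray

    @property
    def loss_fraction(self) -> float:
        """Fraction of tissue-contact A-lines with no resolvable boundary."""
        contact = self.masks.contact
        return float(self.loss[contact].sum() / contact.sum())


def _edge_taper_db_map(contact: np.ndarray, taper: int, depth_db: float) -> np.ndarray:
    """Per-(f, y) dB reduction: linear roll-off over ``taper`` frames at
    each end of every azimuthal contact run."""
    F, Y = contact.shape
    out = np.zeros((F, Y))
    if taper <= 0 or depth_db <= 0:
        return out
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
            for d in range(min(taper, f - start)):
                atten = depth_db * (1.0 - (d + 1) / (taper + 1))
                out[start + d, y] = max(out[start + d, y], atten)
                out[f - 1 - d, y] = max(out[f - 1 - d, y], atten)
    return out


def generate(spec: PhantomSpec) -> tuple[OctVolume, PhantomTruth]:
    """Generate a phantom volume and its ground truth.

    Same seed, same spec → bit-identical output.
    """
    spec.validate()
    F, Y, Z = spec.n_frames, spec.n_pullback, spec.n_depth
    dz_mm = spec.z_spacing_um / 1000.0

    contact = spec._mask(spec.contact_mask, True)
    loss = spec._mask(spec.loss_mask, False) & contact
    bubbles = spec._mask(spec.bubble_mask, False)
    lesion = spec._mask(spec.lesion_mask, False)

    top_mm = spec._field(spec.surface_z_um) / 1000.0
    depth_mm = spec._field(spec.epi_depth_um) / 1000.0
    mu_e = spec._field(spec.mu_epi_mm)
    mu_s = spec._field(spec.mu_stroma_mm)

    bnd_mm = top_mm + depth_mm
    grid_mm = Z * dz_mm
    deep = contact & ~loss & (bnd_mm >= grid_mm)
    if deep.any():
        raise ValueError("epithelium extends deeper than the depth grid")

    # quantize the layer interfaces to the pixel grid so that layer
    # membership, path lengths, and the truth surfaces agree exactly
    top_idx = np.round(top_mm / dz_mm)
    bnd_idx = np.round(bnd_mm / dz_mm)
    zi = np.arange(Z)  # (Z,)
    z = zi * dz_mm
    top3 = (top_idx * dz_mm)[:, :, None]
    # in loss regions the boundary is pushed past the grid: epithelium-like
    # decay continues to the floor and no stromal step occurs
    bnd3 = np.where(loss, np.inf, bnd_idx * dz_mm)[:, :, None]
    ti3 = top_idx[:, :, None]
    bi3 = np.where(loss, np.inf, bnd_idx)[:, :, None]
    e_path = np.clip(z - top3, 0.0, bnd3 - top3)
    s_path = np.clip(z - bnd3, 0.0, None)
    s_path[~np.isfinite(s_path)] = 0.0

    # Single-scattering consistency: backscattered power proportional to
    # the scattering coefficient.  On the discrete grid the unbiased form
    # is B proportional to 1 - exp(-2 mu dz); the default epithelium
    # amplitude follows it (relative to stroma), an explicit value overrides.
    b_s = spec.backscatter_stroma
    if spec.backscatter_epi is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            b_e = b_s * (-np.expm1(-2.0 * mu_e * dz_mm)) / (-np.expm1(-2.0 * mu_s * dz_mm))
        b_e = np.where(np.isfinite(b_e), b_e, b_s)
    else:
        b_e = np.broadcast_to(float(spec.backscatter_epi), spec.enface_shape)
    amp = np.where(zi < ti3, 0.0, np.where(zi < bi3, b_e[:, :, None], b_s))
    power = amp * np.exp(-2.0 * (mu_e[:, :, None] * e_path + mu_s[:, :, None] * s_path))

    power[bubbles] *= 10.0 ** (-spec.bubble_shadow_db / 10.0)
    power[~contact] = 0.0
    taper = _edge_taper_db_map(contact, spec.edge_taper_frames, spec.edge_taper_db)
    power *= 10.0 ** (-taper[:, :, None] / 10.0)

    if spec.speckle:
        rng = np.random.default_rng(spec.seed)
        power = power * rng.exponential(1.0, size=power.shape)

    if spec.noise_floor_db is not None:
        power = power + 10.0 ** (spec.noise_floor_db / 10.0)

    intensity_db = 10.0 * np.log10(np.maximum(power, 1e-30))

    volume = OctVolume(
        intensity_db=intensity_db.astype(np.float32),
        y_spacing_um=spec.y_spacing_um,
        z_spacing_optical_um=spec.z_spacing_um * spec.n_medium,
        n_medium=spec.n_medium,
        frames_per_rev=F,
    )

    epi_top = np.where(contact, top_idx, np.nan)
    boundary = np.where(contact & ~loss, bnd_idx, np.nan)
    truth = PhantomTruth(
        surfaces=SurfaceSet(epi_top=epi_top, boundary=boundary),
        masks=EnFaceMaskSet(contact=contact, artifact=bubbles, lesion=lesion),
        depth_um=np.where(contact, spec._field(spec.epi_depth_um), np.nan),
        mu_epi=np.where(contact, mu_e, np.nan),
        mu_stroma=np.where(contact & ~loss, mu_s, np.nan),
        loss=loss,
    )
    return volume, truth


def preset(
    profile: str,
    n_frames: int = 64,
    n_pullback: int = 512,
    seed: int = 0,
) -> PhantomSpec:
    """Named phantom configurations with parameters drawn from reported
    group medians for lateral/ventral tongue.

    * ``contralateral`` — lesion-free reference: 160 µm epithelium,
      μ_e = 1.20 mm^-1, μ_s = 3.97 mm^-1, no loss of boundary.
    * ``observation_lesion`` — benign/mild/moderate-dysplasia-like:
      thicker epithelium, a small loss-of-boundary patch, bubble artifacts,
      a labelled lesion area.
    * ``intervention_lesion`` — severe-dysplasia/carcinoma-like: the
      boundary is unresolvable over 77% of tissue A-lines.
    """
    if profile not in _PRESETS:
        raise ValueError(f"unknown profile {profile!r}; expected one of {_PRESETS}")

    F, Y = n_frames, n_pullback
    contact = np.zeros((F, Y), dtype=bool)
    band = max(F // 8, 1)
    contact[band : F - band, :] = True  # ~75% azimuthal tissue contact

    spec = PhantomSpec(
        n_frames=F, n_pullback=Y, contact_mask=contact, seed=seed
    )
    if profile == "contralateral":
        return spec

    if profile == "observation_lesion":
        loss = np.zeros((F, Y), dtype=bool)
        loss[:, : int(round(0.06 * Y))] = True
        bubbles = np.zeros((F, Y), dtype=bool)
        bubbles[:, int(0.55 * Y) : int(0.55 * Y) + max(Y // 64, 1)] = True
        lesion = np.zeros((F, Y), dtype=bool)
        lesion[:, Y // 4 : 3 * Y // 4] = True
        return replace(
            spec,
            epi_depth_um=280.0,
            mu_epi_mm=1.45,
            mu_stroma_mm=3.70,
            loss_mask=loss,
            bubble_mask=bubbles,
            lesion_mask=lesion,
        )

    # intervention_lesion: majority loss of the epithelial-stromal boundary
    loss = np.zeros((F, Y), dtype=bool)
    loss[:, : int(round(0.77 * Y))] = True
    lesion = contact.copy()
    return replace(
        spec,
        epi_depth_um=400.0,
        mu_epi_mm=1.60,
        mu_stroma_mm=3.10,
        loss_mask=loss,
        lesion_mask=lesion,
    )


_SCALAR_KEYS = (
    "n_frames",
    "n_pullback",
    "n_depth",
    "y_spacing_um",
    "z_spacing_um",
    "n_medium",
    "epi_depth_um",
    "mu_epi_mm",
    "mu_stroma_mm",
    "backscatter_epi",
    "backscatter_stroma",
    "surface_z_um",
    "noise_floor_db",
    "speckle",
    "edge_taper_frames",
    "edge_taper_db",
    "bubble_shadow_db",
    "seed",
)


def load_spec(path: str | Path) -> PhantomSpec:
    """Read a PhantomSpec from YAML/JSON.

    The file may set any scalar field, start from a named ``profile``, and
    give en face regions as fractions: ``loss_fraction``, ``lesion_fraction``
    (leading fraction of pullback columns within contact).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", None)
    loss_fraction = raw.pop("loss_fraction", None)
    lesion_fraction = raw.pop("lesion_fraction", None)
    unknown = set(raw) - set(_SCALAR_KEYS)
    if unknown:
        raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
    if profile is not None:
        spec = preset(
            profile,
            n_frames=raw.pop("n_frames", 64),
            n_pullback=raw.pop("n_pullback", 512),
            seed=raw.pop("seed", 0),
        )
        spec = replace(spec, **raw)
    else:
        spec = PhantomSpec(**raw)
    for name, frac in (("loss_mask", loss_fraction), ("lesion_mask", lesion_fraction)):
        if frac is not None:
            mask = np.zeros(spec.enface_shape, dtype=bool)
            mask[:, : int(round(float(frac) * spec.n_pullback))] = True
            spec = replace(spec, **{name: mask})
    return spec
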