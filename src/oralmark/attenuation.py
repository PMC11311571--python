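"""Depth-resolved attenuation-coefficient estimation.

The attenuation coefficient μ (mm^-1) is the exponential decay rate of
the OCT signal with depth under the single-scattering round-trip model
P(z) ∝ exp(-2 μ z).  The depth-resolved estimator converts each A-line's
remaining integrated signal into a per-pixel estimate:

    ratio form:  μ[i] = I[i] / (2 (Δ Σ_{j>i} I[j] + T))
    log form:    μ[i] = ln(1 + Δ I[i] / (Δ Σ_{j>i} I[j] + T)) / (2 Δ)

where Δ is the axial pixel size in mm and T compensates the truncated
tail of the integral.  T is closed with a geometric series,
T = Δ I[N-1] r / (1 - r) with r = exp(-2 μ_tail Δ) and μ_tail fitted by
log-linear least squares on the last ``tail_px`` pixels; for small μΔ
this reduces to the familiar I[N-1] / (2 μ_tail).  The log form is exact
on noiseless exponentials (the ratio form carries an O(μΔ) discretization
bias) and is the pipeline default.

Estimation runs over the visualized region of each A-line (epithelium
surface down to the 6 dB-above-noise-floor bottom) on noise-floor-
subtracted linear power.  No confocal/PSF correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .regions import RegionMasks
from .volume_io import EnFaceMap, OctVolume

#: Axial pixel size on the isotropic grid, mm.
DELTA_MM = 0.01

#: Default length of the log-linear tail fit, pixels (100 µm).
TAIL_FIT_PX = 10

#: Default lateral (pullback) moving-average width for speckle reduction.
LATERAL_AVG_PX = 5


@dataclass
class AttenuationVolume:
    """Per-pixel attenuation coefficient, mm^-1; NaN outside the
    visualized region.  ``degenerate_tail`` flags A-lines where the tail
    fit did not decay and compensation fell back to the plain sum."""

    mu: np.ndarray
    delta_mm: float = DELTA_MM
    degenerate_tail: np.ndarray | None = None


def _tail_mu(log_power: np.ndarray, delta_mm: float) -> float:
    """μ from the slope of ln(power) on the tail window (least squares)."""
    n = log_power.size
    x = np.arange(n) - (n - 1) / 2.0
    slope = float(x @ (log_power - log_power.mean()) / (x @ x))
    return -slope / (2.0 * delta_mm)


def depth_resolved_mu(
    power: np.ndarray,
    delta_mm: float = DELTA_MM,
    tail_px: int = TAIL_FIT_PX,
    method: str = "log",
    compensate: bool = True,
) -> tuple[np.ndarray, bool]:
    """Depth-resolved μ profile for one A-line of linear power.

    Parameters
    ----------
    power
        Strictly positive linear power over the N visualized pixels.
    delta_mm
        Pixel size, mm.
    tail_px
        Window for the boundary-condition (tail) fit.
    method
        ``"log"`` (exact on noiseless exponentials, default) or
        ``"ratio"`` (the linearized estimator).
    compensate
        Apply the geometric tail closure.  When off, the deepest pixel has
        no deeper signal to normalize against and is returned as NaN.

    Returns
    -------
    (mu, degenerate)
        μ profile (mm^-1, clipped at 0) and a flag set when the tail fit
        failed to decay and compensation was dropped.
    """
    power = np.asarray(power, dtype=np.float64)
    if power.ndim != 1:
        raise ValueError("power must be a 1-D A-line profile")
    if np.any(power <= 0) or not np.all(np.isfinite(power)):
        raise ValueError("power must be strictly positive and finite")
    n = power.size
    if compensate and n < tail_px:
        raise ValueError(f"need at least tail_px={tail_px} pixels, got {n}")

    # Δ Σ_{j>i} I[j]
    s = delta_mm * (np.cumsum(power[::-1])[::-1] - power)

    degenerate = False
    t = 0.0
    if compensate:
        mu_tail = _tail_mu(np.log(power[-tail_px:]), delta_mm)
        if mu_tail > 0:
            r = np.exp(-2.0 * mu_tail * delta_mm)
            t = delta_mm * power[-1] * r / (1.0 - r)
        else:
            degenerate = True

    denom = s + t
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "log":
            mu = np.log1p(delta_mm * power / denom) / (2.0 * delta_mm)
        elif method == "ratio":
            mu = power / (2.0 * denom)
        else:
            raise ValueError(f"unknown method {method!r}")
    mu = np.maximum(mu, 0.0)  # NaN-propagating clip
    mu[np.isinf(mu)] = np.nan
    return mu, degenerate


def attenuation_volume(
    volume: OctVolume,
    masks: RegionMasks,
    floors_db: np.ndarray,
    delta_mm: float = DELTA_MM,
    tail_px: int = TAIL_FIT_PX,
    lateral_avg: int = LATERAL_AVG_PX,
    method: str = "log",
) -> AttenuationVolume:
    """Vectorized depth-resolved μ over every visualized A-line.

    dB intensity is converted to linear power, the per-frame noise floor is
    subtracted, and a ``lateral_avg``-wide moving average along the
    pullback axis suppresses speckle before estimation.  μ is NaN outside
    the visualized mask.
    """
    intensity = volume.intensity_db.astype(np.float64)
    F, Y, Z = intensity.shape
    power = 10.0 ** (intensity / 10.0)
    floor_lin = 10.0 ** (np.asarray(floors_db, dtype=np.float64) / 10.0)
    power = power - floor_lin[:, None, None]
    tiny = float(floor_lin.min()) * 1e-6 + 1e-300
    power = np.maximum(power, tiny)
    if lateral_avg > 1:
        power = ndimage.uniform_filter1d(power, lateral_avg, axis=1, mode="nearest")

    vis = masks.visualized
    pm = np.where(vis, power, 0.0)
    s = delta_mm * (np.cumsum(pm[:, :, ::-1], axis=2)[:, :, ::-1] - pm)

    # tail fit over the deepest tail_px visualized pixels of each A-line
    n_vis = vis.sum(axis=2)
    fit = n_vis >= tail_px
    bottom = np.where(vis.any(axis=2), Z - np.argmax(vis[:, :, ::-1], axis=2), 0)
    start = np.maximum(bottom - tail_px, 0)
    idx = start[:, :, None] + np.arange(tail_px)[None, None, :]
    tail = np.take_along_axis(np.maximum(pm, tiny), idx, axis=2)
    logt = np.log(tail)
    x = np.arange(tail_px) - (tail_px - 1) / 2.0
    slope = (logt * x).sum(axis=2) / (x @ x)
    mu_tail = -slope / (2.0 * delta_mm)

    last = np.take_along_axis(pm, np.maximum(bottom - 1, 0)[:, :, None], axis=2)[:, :, 0]
    good = fit & (mu_tail > 0)
    r = np.exp(-2.0 * np.where(good, mu_tail, 1.0) * delta_mm)
    t = np.where(good, delta_mm * last * r / (1.0 - r), 0.0)

    denom = s + t[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "log":
            mu = np.log1p(delta_mm * pm / denom) / (2.0 * delta_mm)
        elif method == "ratio":
            mu = pm / (2.0 * denom)
        else:
            raise ValueError(f"unknown method {method!r}")
    mu = np.where(vis & np.isfinite(mu), np.fmax(mu, 0.0), np.nan)
    return AttenuationVolume(
        mu=mu, delta_mm=delta_mm, degenerate_tail=masks.tissue & ~good
    )


_REGION_ATTR = {
    "overall": "visualized",
    "epithelium": "epithelium",
    "stroma": "stroma",
    "upper_epithelium": "upper_epi",
    "lower_epithelium": "lower_epi",
}


def region_mean_mu(
    att: AttenuationVolume, masks: RegionMasks, which: str = "overall"
) -> EnFaceMap:
    """Per-A-line mean μ over a tissue region, as an en face map.

    ``which`` is one of overall, epithelium, stroma, upper_epithelium,
    lower_epithelium.  Entries are NaN where the region is empty — e.g.
    the stroma of a loss-of-boundary A-line.
    """
    try:
        region = getattr(masks, _REGION_ATTR[which])
    except KeyError:
        raise ValueError(
            f"unknown region {which!r}; expected one of {sorted(_REGION_ATTR)}"
        ) from None
    if region.shape != att.mu.shape:
        raise ValueError("region masks are not aligned with the attenuation volume")
    valid = region & np.isfinite(att.mu)
    count = valid.sum(axis=2)
    total = np.where(valid, att.mu, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return EnFaceMap(values, units="mm^-1")
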