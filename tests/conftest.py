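"""Shared fixtures: small deterministic phantoms and volumes."""

import numpy as np
import pytest

from oralmark.phantom import PhantomSpec, generate
from oralmark.volume_io import OctVolume


@pytest.fixture
def small_volume() -> OctVolume:
    rng = np.random.default_rng(42)
    data = rng.normal(-40.0, 5.0, size=(4, 12, 30)).astype(np.float32)
    return OctVolume(
        intensity_db=data,
        y_spacing_um=10.0,
        z_spacing_optical_um=13.33,
        n_medium=1.333,
        frames_per_rev=4,
    )


@pytest.fixture
def tiny_noiseless():
    """Tiny noiseless two-layer phantom with full contact and no taper."""
    # depth grid deep enough that the bottom 25 rows (noise-floor window)
    # are signal-free
    spec = PhantomSpec(
        n_frames=4,
        n_pullback=16,
        n_depth=240,
        epi_depth_um=160.0,
        mu_epi_mm=1.2,
        mu_stroma_mm=3.97,
        surface_z_um=50.0,
        speckle=False,
        edge_taper_frames=0,
        seed=0,
    )
    return generate(spec)
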