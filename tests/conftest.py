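import numpy as np
import pytest

from mechanoquant import synthgen
from mechanoquant.containers import Substrate


@pytest.fixture(scope="session")
def nc_scene_clean():
    """One clean r=20 px disk nucleus, nuclear 200 / ring 100."""
    return synthgen.make_nc_scene(
        1, shape=(128, 128), radius_range=(20.0, 20.0), noise_sd=0.0, seed=0
    )


@pytest.fixture(scope="session")
def nc_scene_noisy():
    """Five nuclei with Gaussian intensity noise, fixed seed."""
    return synthgen.make_nc_scene(5, noise_sd=5.0, seed=42)


@pytest.fixture(scope="session")
def substrate_10kpa():
    return Substrate(youngs_modulus=1e4, poisson_ratio=0.5, regularization=1e-4)


@pytest.fixture(scope="session")
def tfm_scene(substrate_10kpa):
    """Bead pair for a contractile traction dipole on a 10 kPa gel."""
    traction = synthgen.traction_dipole(
        (512, 512), peak_pa=400.0, sigma_um=3.0, separation_um=18.0, pixel_size=0.1
    )
    deformed, relaxed, mask, gt = synthgen.make_tfm_pair(
        traction, substrate_10kpa, noise_sd=2.0, seed=3
    )
    return traction, deformed, relaxed, mask, gt


def true_avg_stress_on_grid(traction, field, node_labels):
    """Ground-truth mean |t| sampled at the grid nodes covered by the mask."""
    oy, ox = field.origin_px
    iy = np.round(oy + np.arange(field.shape[0]) * field.spacing_px).astype(int)
    ix = np.round(ox + np.arange(field.shape[1]) * field.spacing_px).astype(int)
    mag = traction.magnitude()[np.ix_(iy, ix)]
    return float(mag[node_labels == 1].mean())
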