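import numpy as np
import pytest

from octme.phantom import OpticsConfig, SceneConfig, render_bscan


@pytest.fixture(scope="session")
def noiseless_optics():
    """Optics with speckle and read noise off (PSF blur stays on)."""
    return OpticsConfig(speckle_contrast=0.0, noise_floor_sd=0.0)


@pytest.fixture(scope="session")
def default_optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def flat_phantom(noiseless_optics):
    """Noiseless flat membrane: tilt 0, d = 30 um, n = 1.44."""
    scene = SceneConfig(tm_thickness_um=30.0, tilt_deg=0.0, ri=1.44, seed=1)
    return render_bscan(noiseless_optics, scene) + (scene,)


@pytest.fixture(scope="session")
def tilted_phantom(noiseless_optics):
    """Noiseless tilted membrane: tilt 55 deg, d = 30 um, n = 1.44."""
    scene = SceneConfig(tm_thickness_um=30.0, tilt_deg=55.0, ri=1.44, seed=2)
    return render_bscan(noiseless_optics, scene) + (scene,)


@pytest.fixture(scope="session")
def biofilm_phantom(noiseless_optics):
    """Noiseless membrane with a thick irregular adherent layer."""
    scene = SceneConfig(
        tm_thickness_um=25.0,
        tilt_deg=45.0,
        ri=1.44,
        biofilm_mean_um=75.0,
        biofilm_cv=0.3,
        seed=3,
    )
    return render_bscan(noiseless_optics, scene) + (scene,)


@pytest.fixture(scope="session")
def watery_phantom(default_optics):
    """Noisy watery-effusion scene, fully filled cavity."""
    scene = SceneConfig(
        tm_thickness_um=28.0,
        tilt_deg=48.0,
        mee_type="watery",
        particle_density_per_mm2=50.0,
        fluid_fill_fraction=1.0,
        seed=4,
    )
    return render_bscan(default_optics, scene) + (scene,)


@pytest.fixture(scope="session")
def dense_phantom(default_optics):
    """Noisy dense-effusion scene (bright tissue-like fill)."""
    scene = SceneConfig(
        tm_thickness_um=28.0,
        tilt_deg=48.0,
        mee_type="dense",
        fluid_fill_fraction=1.0,
        seed=5,
    )
    return render_bscan(default_optics, scene) + (scene,)


@pytest.fixture(scope="session")
def clear_phantom(default_optics):
    """Noisy clear middle ear."""
    scene = SceneConfig(tm_thickness_um=26.0, tilt_deg=48.0, mee_type="clear", seed=6)
    return render_bscan(default_optics, scene) + (scene,)


def measure_band_extent_rows(scan, truth, column=None):
    """Half-maximum axial extent (rows) of the rendered band at one column.

    Independent of the segmentation code: scans the raw pixel profile for
    the first/last crossing of the level midway between background and
    band plateau.
    """
    if column is None:
        vcols = np.flatnonzero(truth.valid)
        column = int(vcols[len(vcols) // 2])
    prof = scan.pixels[:, column]
    lo, hi = float(prof.min()), float(prof.max())
    level = lo + 0.5 * (hi - lo)
    above = np.flatnonzero(prof >= level)
    first, last = above[0], above[-1]
    top = first + 0.5
    if first > 0 and prof[first] > prof[first - 1]:
        top -= (prof[first] - level) / (prof[first] - prof[first - 1])
    bot = last + 0.5
    if last < prof.size - 1 and prof[last] > prof[last + 1]:
        bot += (prof[last] - level) / (prof[last] - prof[last + 1])
    return bot - top
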