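import numpy as np
import pytest

from mrsipvc import (
    AcquisitionGeometry,
    PhantomSpec,
    QADefect,
    Structure,
    build_elliptical_shutter,
    build_psf,
    generate_study,
)


@pytest.fixture(scope="session")
def geometry():
    """Full default acquisition geometry (44 x 44, 220 mm FOV, 2 slices)."""
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def default_psf(geometry):
    return build_psf(geometry, build_elliptical_shutter(geometry))


@pytest.fixture(scope="session")
def small_geometry():
    """A 12 x 12 single-slice slab (60 x 60 x 10 mm) for fast tests."""
    return AcquisitionGeometry(
        fov_mm=(60.0, 60.0), acq_matrix=(12, 12), n_slices=1
    )


def small_phantom_spec(seed=0, noise_sd=0.0, with_defects=False):
    """Miniature brain slab: WM ellipse, GM ribbon, ventricle, GM nucleus."""
    structures = [
        Structure("brain", "ellipse", {"wm": 1.0},
                  {"center": (30.0, 30.0), "semi_axes": (24.0, 27.0)}),
        Structure("cortex", "shell", {"gm": 1.0},
                  {"center": (30.0, 30.0), "semi_axes": (24.0, 27.0),
                   "thickness": 4.0}),
        Structure("ventricle", "ellipse", {"csf": 1.0},
                  {"center": (37.0, 30.0), "semi_axes": (4.0, 9.0)}),
        Structure("nucleus", "ellipse", {"gm": 1.0},
                  {"center": (22.0, 30.0), "semi_axes": (6.0, 8.0)}),
    ]
    defects = []
    if with_defects:
        defects = [
            QADefect("overcrushed_rim", "annulus",
                     {"center": (5.5, 5.5), "semi_axes": (4.8, 5.4),
                      "width": 1.2},
                     {"snr": 1.0}),
        ]
    return PhantomSpec(
        slab_shape=(60, 60, 10),
        structures=structures,
        pure_values={"Glu": (1.2, 0.7)},
        noise_sd=noise_sd,
        qa_defects=defects,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study(small_geometry):
    """Noiseless miniature study, the workhorse for exact-recovery tests."""
    return generate_study(small_phantom_spec(), geometry=small_geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
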