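import numpy as np
import pytest

from whiskvib import morph, synth


def rasterize_ellipse(a: float, b: float, theta_deg: float, n: int | None = None):
    """Analytic digitized ellipse mask (pixel-center inclusion test)."""
    if n is None:
        n = int(2 * a + 10)
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    t = np.deg2rad(theta_deg)
    xr = (xx - c) * np.cos(t) + (yy - c) * np.sin(t)
    yr = -(xx - c) * np.sin(t) + (yy - c) * np.cos(t)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1


def angle_distance(a: float, b: float) -> float:
    """Distance between two axis orientations, accounting for the 180-deg wrap."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@pytest.fixture(scope="session")
def undulated_phantom():
    """Undulated phantom with several wavelengths at scan resolution."""
    spec = synth.undulated_archetype(
        length=12.0, undulation_wavelength=2.0, undulation_relative_amplitude=0.2,
        base_eccentricity=0.8, tip_eccentricity=0.9, seed=5,
    )
    return synth.generate_phantom(spec)


@pytest.fixture(scope="session")
def undulated_profile(undulated_phantom):
    return morph.profile_along_shaft(
        undulated_phantom.volume, undulated_phantom.voxel_size_um, threshold=127
    )


@pytest.fixture(scope="session")
def smooth_phantom():
    spec = synth.smooth_archetype(length=12.0, seed=7)
    return synth.generate_phantom(spec)


@pytest.fixture(scope="session")
def smooth_profile(smooth_phantom):
    return morph.profile_along_shaft(
        smooth_phantom.volume, smooth_phantom.voxel_size_um, threshold=127
    )


@pytest.fixture(scope="session")
def default_table():
    return synth.generate_study_table(synth.default_study_design(seed=1))
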