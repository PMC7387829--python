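import numpy as np
import pytest

from blurfield.eye import ConicSurface, EyeModel, build_eye


@pytest.fixture(scope="session")
def eye550():
    """The wide-angle schematic eye at the working wavelength."""
    return build_eye(550.0)


@pytest.fixture(scope="session")
def index_matched_eye():
    """Synthetic zero-aberration fixture: all media at n = 1 (no refraction)
    and a plane image surface, so every wavefront is identically flat."""
    surfs = []
    z = 0.0
    for thick in (0.55, 3.05, 4.0, 16.3203):
        surfs.append(ConicSurface(vertex_mm=z, radius_mm=7.72, conic=0.0,
                                  index_before=1.0, index_after=1.0,
                                  semi_aperture_mm=6.0))
        z += thick
    retina = ConicSurface(vertex_mm=z, radius_mm=np.inf, conic=0.0,
                          index_before=1.0, index_after=1.0,
                          semi_aperture_mm=12.0)
    return EyeModel(surfaces=tuple(surfs), retina=retina, wavelength_nm=550.0,
                    stop_z_mm=3.6, name="index-matched synthetic eye")


@pytest.fixture(scope="session")
def small_stimulus():
    from blurfield.stimulus import generate_binary_noise
    return generate_binary_noise(seed=11, size_px=1080,
                                 scale_arcmin=15.0 * 60 / 1080)
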