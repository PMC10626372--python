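import numpy as np
import pytest

from fetcu import BinaryMask, PhantomSpec, SuvVolume, build_radial_profile


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    affine = np.diag([*spacing, 1.0])
    return SuvVolume(np.asarray(values, dtype=float), affine)


def make_mask(values, spacing=(1.0, 1.0, 1.0), label="lesion"):
    affine = np.diag([*spacing, 1.0])
    return BinaryMask(np.asarray(values), affine, label)


def cone_spec(scale=20.0, **overrides):
    """Phantom whose isocontour radii are (0.20, 0.25, 0.40)*scale mm.

    The linear-cone reference geometry: volumetric CU ratio
    (0.40^3 - 0.25^3)/0.20^3 = 6.046875 exactly.
    """
    v = lambda r: 4.0 / 3.0 * np.pi * r**3 / 1000.0
    r80, r75, r60 = 0.20 * scale, 0.25 * scale, 0.40 * scale
    v_central = v(r80)
    v_gap = v(r75) - v(r80)
    v_peripheral = v(r60) - v(r75)
    kwargs = dict(
        v_central=v_central,
        v_peripheral=v_peripheral,
        gap_fraction=v_gap / v_peripheral,
        suv_max=3.0,
        background_suv=1.0,
        grid_shape=(48, 48, 48),
        spacing_mm=(1.0, 1.0, 1.0),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture
def default_phantom():
    spec = PhantomSpec()
    truth, profile = build_radial_profile(spec)
    return spec, truth, profile


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
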