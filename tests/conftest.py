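import numpy as np
import pytest

from cereflow import TubeSpec, make_bifurcation_phantom, make_tube_phantom

# 0.4 mm voxels: 10 voxels across the 4 mm tube diameter


@pytest.fixture(scope="session")
def straight_tube():
    """Noiseless axis-aligned Poiseuille tube: R = 2 mm, v_max = 0.5 m/s,
    ~40 mm long, axis along x through a voxel-center line."""
    spacing = (0.4, 0.4, 0.4)
    shape = (24, 24, 110)
    c = (np.array(shape) - 1) / 2 * 0.4
    spec = TubeSpec(
        start=[c[0], c[1], 2.4],
        end=[c[0], c[1], 41.0],
        radius_mm=2.0,
        v_max=0.5,
        label="tube",
    )
    vol, truth = make_tube_phantom(spec, shape, spacing)
    return spec, vol, truth


@pytest.fixture(scope="session")
def stenosed_tube():
    """Severely stenosed tube (70% diameter reduction at mid-length)."""
    spacing = (0.4, 0.4, 0.4)
    shape = (24, 24, 110)
    c = (np.array(shape) - 1) / 2 * 0.4
    spec = TubeSpec(
        start=[c[0], c[1], 2.4],
        end=[c[0], c[1], 41.0],
        radius_mm=2.0,
        v_max=0.5,
        stenosis_grade=0.7,
        stenosis_center=0.5,
        stenosis_width_mm=2.0,
        label="stenosed",
    )
    vol, truth = make_tube_phantom(spec, shape, spacing)
    return spec, vol, truth


@pytest.fixture(scope="session")
def bifurcation():
    """Parent (R=2 mm) splitting 60/40 into two R=1.6 mm daughters; all
    vessels at >= 8 voxels per diameter."""
    shape = (60, 80, 80)
    spacing = (0.4, 0.4, 0.4)
    ext = (np.array(shape) - 1) * 0.4
    junction = np.array([ext[0] / 2, ext[1] / 2, ext[2] * 0.5])
    parent = TubeSpec(
        start=[junction[0], ext[1] / 2, 3.0], end=junction,
        radius_mm=2.0, v_max=0.5, label="ICA",
    )
    d1 = TubeSpec(
        start=junction, end=[junction[0], ext[1] * 0.85, ext[2] * 0.85],
        radius_mm=1.6, label="MCA",
    )
    d2 = TubeSpec(
        start=junction, end=[junction[0], ext[1] * 0.15, ext[2] * 0.85],
        radius_mm=1.6, label="ACA",
    )
    vol, truth = make_bifurcation_phantom(
        parent, (d1, d2), split=0.6, shape=shape, spacing=spacing
    )
    return vol, truth
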