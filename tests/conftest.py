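import numpy as np
import pytest

from tavrseal import anatomy, deployment, frame

COARSE = (48, 24)  # fast anatomy resolution for deployment-heavy tests


def make_tube(radius: float, z_lo: float, z_hi: float, circ: int = 48,
              rings: int = 12, region: str = anatomy.LVOT) -> anatomy.AorticRootMesh:
    """Plain cylindrical tube mesh with a uniform region label."""
    theta = np.arange(circ) * 2 * np.pi / circ
    zs = np.linspace(z_lo, z_hi, rings)
    verts = np.array([
        [radius * np.cos(t), radius * np.sin(t), z]
        for z in zs for t in theta
    ])
    tris = []
    for i in range(rings - 1):
        for j in range(circ):
            j1 = (j + 1) % circ
            v00, v01 = i * circ + j, i * circ + j1
            v10, v11 = (i + 1) * circ + j, (i + 1) * circ + j1
            tris.append((v00, v01, v11))
            tris.append((v00, v11, v10))
    tris = np.array(tris, int)
    labels = np.full(len(tris), region, dtype="U24")
    mats = np.full(len(tris), anatomy.WALL, dtype="U24")
    return anatomy.AorticRootMesh(verts, tris, labels, mats)


@pytest.fixture(scope="session")
def tav_mesh():
    params = anatomy.RootParams("TAV", 25.0, 25.0)
    return anatomy.build_root(params)


@pytest.fixture(scope="session")
def frame26():
    return frame.build_frame(frame.FrameParams(size_label=26))


@pytest.fixture(scope="session")
def crimped26(frame26):
    return frame.crimp(frame26, 8.0)


@pytest.fixture(scope="session")
def deployed_tav(crimped26):
    """A representative deployed state: size-26 frame in a mildly elliptical
    TAV root with one calcific deposit."""
    params = anatomy.RootParams("TAV", 25.0, 22.0, mesh_resolution=COARSE,
                                triangle_recess=0.8)
    root = anatomy.place_calcium(
        anatomy.build_root(params),
        [anatomy.CalciumDeposit(1.0, 8.0, 0.8, 7.0, 500.0, 2.0)],
    )
    return deployment.deploy(crimped26, root, 6.0)
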