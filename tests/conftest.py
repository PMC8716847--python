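import numpy as np
import pytest

from cardioem.geometry import (HeartMesh, LVGeometry, _edge_midpoint_refine,
                               _orient_tets, _tets_from_hexes,
                               build_lv_ellipsoid)


@pytest.fixture(scope="session")
def lv_geometry():
    return LVGeometry()


@pytest.fixture(scope="session")
def lv_meshes(lv_geometry):
    """Default idealized LV at EP and mechanics resolutions."""
    return build_lv_ellipsoid(lv_geometry)


@pytest.fixture(scope="session")
def lv_meshes_coarse(lv_geometry):
    """Coarser variant for expensive mechanics tests."""
    return build_lv_ellipsoid(lv_geometry, ep_edge=4.5, mech_edge=13.0)


def make_block(nv=3, lx=1.0, fibers=((1, 0, 0), (0, 1, 0), (0, 0, 1))):
    """Structured quadratic-tet block on [0, lx]^3 with uniform fibers."""
    g = np.arange(nv) / (nv - 1) * lx
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], 1)
    idx = np.arange(nv**3).reshape(nv, nv, nv)
    hexes = []
    for i in range(nv - 1):
        for j in range(nv - 1):
            for k in range(nv - 1):
                h = np.empty((1, 2, 2, 2), dtype=np.int64)
                for di in range(2):
                    for dj in range(2):
                        for dk in range(2):
                            h[0, di, dj, dk] = idx[i + di, j + dj, k + dk]
                hexes.append(h)
    tets = _orient_tets(nodes, _tets_from_hexes(np.concatenate(hexes)))
    n10, e10, _ = _edge_midpoint_refine(nodes, tets)
    E = len(e10)
    f, s, sn = (np.tile(v, (E, 1)).astype(float) for v in fibers)
    return HeartMesh(nodes=n10, elems=e10, order=2, dim=3,
                     fiber_f=f, fiber_s=s, fiber_sn=sn,
                     transmural=np.zeros(len(n10)),
                     apicobasal=np.zeros(len(n10)))


@pytest.fixture(scope="session")
def block_mesh():
    return make_block()


@pytest.fixture()
def symmetry_mask(block_mesh):
    """Per-DOF mask fixing normal displacement on the x=y=z=0 planes."""
    n10 = block_mesh.nodes
    mask = np.zeros((len(n10), 3), dtype=bool)
    for d in range(3):
        mask[np.abs(n10[:, d]) < 1e-12, d] = True
    return mask
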