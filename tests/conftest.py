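import numpy as np
import pytest
import trimesh

from orbifab import phantom
from orbifab.pipeline import _defect_cap_meshes


@pytest.fixture(scope="session")
def default_phantom():
    """Default noisy shell phantom (volume, ground-truth mask, spec)."""
    spec = phantom.PhantomSpec(seed=3)
    vol, truth = phantom.make_orbital_phantom(spec)
    return vol, truth, spec


@pytest.fixture(scope="session")
def cap_pair():
    """Intact and defect mid-surface cap meshes for the template chain."""
    spec = phantom.PhantomSpec(defect_angle_deg=40)
    intact, damaged = _defect_cap_meshes(spec)
    return intact, damaged, spec


@pytest.fixture(scope="session")
def plate_with_hole():
    """Planar triangulated plate with an exact circular hole of radius 4."""
    from scipy.spatial import Delaunay

    n = 40
    gx, gy = np.meshgrid(np.linspace(-10, 10, n), np.linspace(-10, 10, n))
    pts2 = np.column_stack([gx.ravel(), gy.ravel()])
    keep = np.linalg.norm(pts2, axis=1) > 4.0
    th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    rim = np.column_stack([4 * np.cos(th), 4 * np.sin(th)])
    pts2 = np.vstack([pts2[keep], rim])
    tri = Delaunay(pts2)
    cent = pts2[tri.simplices].mean(axis=1)
    fk = np.linalg.norm(cent, axis=1) > 4.0
    plate = trimesh.Trimesh(
        vertices=np.column_stack([pts2, np.zeros(len(pts2))]),
        faces=tri.simplices[fk],
        process=False,
    )
    trimesh.repair.fix_normals(plate)
    return plate, th
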