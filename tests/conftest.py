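import functools

import numpy as np
import pytest

import mandrelsim as ms
from mandrelsim.catheter_sim import RayCaster


@functools.lru_cache(maxsize=None)
def _bundle(kind: str):
    """Phantom + computed centerline + ray caster, built once per kind."""
    spec = ms.PhantomSpec(kind=kind)
    ph = ms.make_phantom(spec)
    mask = np.asarray(ph.mask.data)
    cl = ms.compute_centerline(
        mask,
        ph.mask.spacing,
        ph.truth_centerline.points[0],
        ph.truth_centerline.points[-1],
        origin=ph.mask.origin,
    )
    return ph, cl, RayCaster(ph.mesh)


@pytest.fixture(scope="session")
def sidewall_bundle():
    return _bundle("sidewall_aneurysm")


@pytest.fixture(scope="session")
def straight_bundle():
    return _bundle("straight_tube")


@pytest.fixture(scope="session")
def bent_bundle():
    return _bundle("bent_tube")


@pytest.fixture(scope="session")
def bifurcation_bundle():
    return _bundle("bifurcation_aneurysm")


@pytest.fixture(scope="session")
def all_bundles(sidewall_bundle, straight_bundle, bent_bundle, bifurcation_bundle):
    return {
        "sidewall_aneurysm": sidewall_bundle,
        "straight_tube": straight_bundle,
        "bent_tube": bent_bundle,
        "bifurcation_aneurysm": bifurcation_bundle,
    }


def winding_contains(mesh, points):
    """Independent containment oracle: generalized winding number via
    the van Oosterom–Strackee solid-angle formula, summed over faces.
    A point is inside a watertight surface iff the total solid angle is
    ~4*pi (winding number ~1)."""
    tri = mesh.vertices[mesh.faces]
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(np.asarray(points, dtype=float)):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", a, c) * lb
        )
        omega = 2.0 * np.arctan2(num, den)
        out[i] = abs(omega.sum() / (4.0 * np.pi)) > 0.5
    return out


def sample_points_in_bbox(volume, n, seed):
    """Uniform world-space samples inside a volume's bounding box."""
    rng = np.random.default_rng(seed)
    lo = volume.origin
    hi = lo + (np.array(volume.data.shape) - 1) * volume.spacing
    return rng.uniform(lo, hi, size=(n, 3))
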