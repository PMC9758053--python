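import numpy as np
import pytest

from bundleforge.geometry import BundleSpec, CrickParams, assemble_bundle
from bundleforge.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def trimer35():
    """Parallel C3 coiled-coil trimer, 35 residues per chain."""
    spec = BundleSpec(
        tuple(CrickParams(supercoil_phase=p, length=35) for p in (0.0, 120.0, 240.0)),
        ("A", "B", "C"),
    )
    return assemble_bundle(spec)


@pytest.fixture(scope="session")
def trimer77():
    """Parallel C3 coiled-coil trimer, 77 residues per chain."""
    spec = BundleSpec(
        tuple(CrickParams(supercoil_phase=p, length=77) for p in (0.0, 120.0, 240.0)),
        ("A", "B", "C"),
    )
    return assemble_bundle(spec)


@pytest.fixture(scope="session")
def planted_triad_fixture():
    return make_fixture(FixtureSpec("planted-triad"))


@pytest.fixture(scope="session")
def c3_wedge_fixture():
    return make_fixture(FixtureSpec("c3-wedge"))


@pytest.fixture(scope="session")
def toy_dhr_fixture():
    return make_fixture(FixtureSpec("toy-dhr"))


def quaternion_superpose(p: np.ndarray, q: np.ndarray):
    """Independent oracle: Horn's closed-form quaternion superposition.

    Returns (rotation, translation, rmsd) of the proper rigid transform
    mapping p onto q, computed from the maximal eigenvector of the 4x4
    quaternion profile matrix rather than an SVD.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    w, x, y, z = vecs[:, np.argmax(vals)]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    tra = q.mean(axis=0) - rot @ p.mean(axis=0)
    diff = p @ rot.T + tra - q
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return rot, tra, rmsd
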