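"""Crick-parameterized helix/bundle generation and rigid-body math.

The generalized Crick parameterization describes an alpha-helix winding
around a superhelical (z) axis.  Each helix is described by a supercoil
radius ``R``, supercoil phase ``dphi0`` (position around the z axis),
helical phase ``dphi1`` (rotation of the helix about its own axis),
per-residue supercoil twist ``omega0`` and helical twist ``omega1``, and a
translation ``z_off`` along the supercoil axis.  With the ideal values
``omega0 = -2.85`` deg/res and ``omega1 = 102.85`` deg/res the helix makes
3.5 residues per turn relative to the supercoil frame, giving the classic
seven-residue (heptad) repeat of left-handed coiled coils.

Full backbones (N, C, O, CB) are produced by decorating the Crick CA trace
with an ideal alpha-helical residue frame whose internal coordinates are
calibrated once so that the helical twist and rise match the CA trace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

# Ideal-helix constants (conventional values for an alpha-helix).
MINOR_RADIUS = 2.26  # Angstrom, helix minor radius R1
RISE_PER_RESIDUE = 1.51  # Angstrom, rise per residue along the helix axis
OMEGA0_IDEAL = -2.85  # deg/residue, left-handed supercoil twist
OMEGA1_IDEAL = 102.85  # deg/residue, 3.5 residues per (supercoil-frame) turn
PHASE_LATTICE = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")
_ATOM_INDEX = {name: i for i, name in enumerate(BACKBONE_ATOMS)}

# Ideal peptide internal coordinates used for frame calibration.
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.5


class GeometryError(ValueError):
    """Invalid geometric input (bad parameters, degenerate selections)."""


# ---------------------------------------------------------------------------
# rigid-body transforms


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise GeometryError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def rotation_about_axis(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        point: Sequence[float] | None = None,
    ) -> "Transform":
        """Rotation by ``angle_deg`` about ``axis`` passing through ``point``."""
        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            raise GeometryError("rotation axis must be non-zero")
        axis = axis / norm
        theta = math.radians(angle_deg)
        kx, ky, kz = axis
        k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        rot = (
            np.eye(3)
            + math.sin(theta) * k_cross
            + (1.0 - math.cos(theta)) * (k_cross @ k_cross)
        )
        if point is None:
            tra = np.zeros(3)
        else:
            point = np.asarray(point, dtype=float)
            tra = point - rot @ point
        return cls(rot, tra)

    @classmethod
    def translation_by(cls, vec: Sequence[float]) -> "Transform":
        return cls(np.eye(3), np.asarray(vec, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        rot_inv = self.rotation.T
        return Transform(rot_inv, -rot_inv @ self.translation)

    def power(self, n: int) -> "Transform":
        if n < 0:
            return self.inverse().power(-n)
        out = Transform.identity()
        for _ in range(n):
            out = self.compose(out)
        return out


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class CrickParams:
    """Per-helix generalized Crick parameters (degrees / Angstrom)."""

    supercoil_radius: float = 7.0
    supercoil_phase: float = 0.0
    helical_phase: float = 0.0
    z_offset: float = 0.0
    supercoil_twist: float = OMEGA0_IDEAL
    helical_twist: float = OMEGA1_IDEAL
    length: int = 77
    inverted: bool = False
    minor_radius: float = MINOR_RADIUS
    rise_per_residue: float = RISE_PER_RESIDUE

    def __post_init__(self) -> None:
        vals = (
            self.supercoil_radius,
            self.supercoil_phase,
            self.helical_phase,
            self.z_offset,
            self.supercoil_twist,
            self.helical_twist,
            self.minor_radius,
            self.rise_per_residue,
        )
        if not all(math.isfinite(v) for v in vals):
            raise GeometryError("CrickParams fields must be finite")
        if self.length < 7:
            raise GeometryError("helix length must be at least 7 residues")
        if self.supercoil_radius < 0:
            raise GeometryError("supercoil radius must be non-negative")
        if self.minor_radius <= 0 or self.rise_per_residue <= 0:
            raise GeometryError("minor radius and rise must be positive")
        s = (
            self.supercoil_radius
            * math.radians(self.supercoil_twist)
            / self.rise_per_residue
        )
        if abs(s) >= 1.0:
            raise GeometryError(
                "supercoil too tight: |R * omega0| must be < rise per residue"
            )

    @property
    def pitch_angle(self) -> float:
        """Supercoil pitch angle alpha in degrees; 0 for a straight helix."""
        s = (
            self.supercoil_radius
            * math.radians(self.supercoil_twist)
            / self.rise_per_residue
        )
        return math.degrees(math.asin(s))

    def replace(self, **kwargs) -> "CrickParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BundleSpec:
    """An ordered collection of helices making up one parametric bundle."""

    helices: tuple[CrickParams, ...]
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        helices = tuple(self.helices)
        object.__setattr__(self, "helices", helices)
        if not helices:
            raise GeometryError("bundle needs at least one helix")
        chain_ids = tuple(self.chain_ids)
        if not chain_ids:
            chain_ids = tuple(_default_chain_id(i) for i in range(len(helices)))
        if len(chain_ids) != len(helices):
            raise GeometryError("chain_ids must match helix count")
        object.__setattr__(self, "chain_ids", chain_ids)
        if abs(helices[0].z_offset) > 1e-9:
            raise GeometryError("first helix must have z_offset = 0")
        for h in helices:
            if _lattice_distance(h.supercoil_phase) > 1e-6:
                raise GeometryError(
                    "supercoil phases restricted to multiples of 60 degrees"
                )


def _default_chain_id(i: int) -> str:
    return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[i % 26]


def _lattice_distance(phase: float) -> float:
    return min(abs((phase % 360.0) - p) for p in list(PHASE_LATTICE) + [360.0])


# ---------------------------------------------------------------------------
# backbone model


@dataclass
class BackboneModel:
    """Multi-chain backbone coordinates with per-residue identity.

    ``coords`` has shape (n_residues, 5, 3) with atom order N, CA, C, O, CB.
    """

    chain_ids: np.ndarray  # (n,) str
    res_ids: np.ndarray  # (n,) int, 1-based within chain
    res_names: np.ndarray  # (n,) str, 3-letter codes
    coords: np.ndarray  # (n, 5, 3) float
    register: np.ndarray | None = None  # (n,) single letters a-g or ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.chain_ids), 5, 3):
            raise GeometryError("coords must have shape (n_residues, 5, 3)")

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(str(c))
        return seen

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_ids == chain

    def chain_slice(self, chain: str) -> "BackboneModel":
        mask = self.chain_mask(chain)
        return BackboneModel(
            self.chain_ids[mask],
            self.res_ids[mask],
            self.res_names[mask],
            self.coords[mask],
            None if self.register is None else self.register[mask],
            dict(self.meta),
        )

    def atom_coords(self, name: str) -> np.ndarray:
        return self.coords[:, _ATOM_INDEX[name], :]

    @property
    def ca(self) -> np.ndarray:
        return self.atom_coords("CA")

    def transformed(self, transform: Transform) -> "BackboneModel":
        out = self.copy()
        out.coords = transform.apply(self.coords.reshape(-1, 3)).reshape(
            self.coords.shape
        )
        return out

    def copy(self) -> "BackboneModel":
        return BackboneModel(
            self.chain_ids.copy(),
            self.res_ids.copy(),
            self.res_names.copy(),
            self.coords.copy(),
            None if self.register is None else self.register.copy(),
            dict(self.meta),
        )

    @staticmethod
    def concatenate(models: Iterable["BackboneModel"]) -> "BackboneModel":
        models = list(models)
        regs = []
        for m in models:
            regs.append(
                m.register
                if m.register is not None
                else np.full(len(m), "", dtype="U1")
            )
        meta: dict = {}
        for m in models:
            meta.update(m.meta)
        return BackboneModel(
            np.concatenate([m.chain_ids for m in models]),
            np.concatenate([m.res_ids for m in models]),
            np.concatenate([m.res_names for m in models]),
            np.concatenate([m.coords for m in models]),
            np.concatenate(regs),
            meta,
        )


# ---------------------------------------------------------------------------
# NeRF and the ideal residue frame


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Natural extension reference frame placement of atom d bonded to c."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB from the backbone frame (correct L-amino-acid chirality)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _build_polyala(phi: float, psi: float, n_res: int) -> dict[str, np.ndarray]:
    """Poly-Ala chain with uniform (phi, psi), omega = 180, by NeRF."""
    ns = np.zeros((n_res, 3))
    cas = np.zeros((n_res, 3))
    cs = np.zeros((n_res, 3))
    ns[0] = [0.0, 0.0, 0.0]
    cas[0] = [_BOND_N_CA, 0.0, 0.0]
    ang = math.radians(_ANG_N_CA_C)
    cs[0] = cas[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        ns[i] = place_atom(ns[i - 1], cas[i - 1], cs[i - 1], _BOND_C_N, _ANG_CA_C_N, psi)
        cas[i] = place_atom(cas[i - 1], cs[i - 1], ns[i], _BOND_N_CA, _ANG_C_N_CA, 180.0)
        cs[i] = place_atom(cs[i - 1], ns[i], cas[i], _BOND_CA_C, _ANG_N_CA_C, phi)
    os_ = np.zeros((n_res, 3))
    for i in range(n_res):
        os_[i] = place_atom(ns[i], cas[i], cs[i], _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
    cbs = np.array([cb_position(ns[i], cas[i], cs[i]) for i in range(n_res)])
    return {"N": ns, "CA": cas, "C": cs, "O": os_, "CB": cbs}


def _helix_twist_rise(ca: np.ndarray) -> tuple[float, float]:
    """Per-residue twist (deg) and rise (A) of a uniform helical CA trace."""
    from scipy.spatial.transform import Rotation

    transform, _ = kabsch(ca[:-1], ca[1:])  # screw mapping residue i -> i+1
    rotvec = Rotation.from_matrix(transform.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    axis = rotvec / angle
    rise = abs(float(np.dot(transform.apply(ca[0]) - ca[0], axis)))
    return math.degrees(angle), rise


def _ca_frames(ca_ext: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local frames at each interior point of an extended CA trace.

    Returns (origins (n,3), rotations (n,3,3)); frame axes are the smoothed
    chain tangent, the inward curvature bisector, and their cross product.
    """
    prev, cur, nxt = ca_ext[:-2], ca_ext[1:-1], ca_ext[2:]
    t = nxt - prev
    t = t / np.linalg.norm(t, axis=1, keepdims=True)
    u = prev + nxt - 2.0 * cur
    u = u - np.sum(u * t, axis=1, keepdims=True) * t
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    # nearly collinear stretch (e.g. an extended linker): any perpendicular
    degenerate = norms[:, 0] < 1e-8
    if degenerate.any():
        ref = np.array([0.0, 0.0, 1.0])
        alt = np.cross(t[degenerate], ref)
        bad = np.linalg.norm(alt, axis=1) < 1e-8
        alt[bad] = np.cross(t[degenerate][bad], np.array([1.0, 0.0, 0.0]))
        u[degenerate] = alt
        norms = np.linalg.norm(u, axis=1, keepdims=True)
    u = u / norms
    v = np.cross(t, u)
    rot = np.stack([t, u, v], axis=2)  # columns t, u, v
    return cur, rot


@lru_cache(maxsize=1)
def _ideal_residue_template() -> dict[str, np.ndarray]:
    """Frame-local offsets of N, C, O, CB for a canonical alpha-helix residue.

    A uniform poly-Ala helix is built at the canonical alpha torsions
    (phi = -57.8, psi = -47.0); the central residue's atoms are expressed in
    the local CA-triplet frame and re-used on arbitrary helical CA traces.
    The exact (102.85 deg, 1.51 A) twist/rise pair of the Crick trace is not
    reachable with ideal peptide bond geometry, so the canonical frame is
    used and the phi/psi of decorated backbones land near, not exactly at,
    the canonical torsions.
    """
    phi, psi = -57.8, -47.0
    chain = _build_polyala(phi, psi, 9)
    origins, rots = _ca_frames(chain["CA"])
    i = 3  # central interior residue (index 4 of the chain)
    origin, rot = origins[i], rots[i]
    local = {
        name: rot.T @ (chain[name][i + 1] - origin) for name in ("N", "C", "O", "CB")
    }
    local["phi_psi"] = np.array([phi, psi])
    return local


def backbone_from_ca(
    ca: np.ndarray, ca_ext: np.ndarray | None = None
) -> np.ndarray:
    """Decorate a CA trace with ideal-frame N, C, O, CB atoms.

    ``ca_ext`` optionally supplies the trace extended by one virtual point at
    each end; otherwise the ends are extrapolated with the chain's own
    per-residue screw transform.
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    if n < 4:
        raise GeometryError("need at least 4 CA positions")
    if ca_ext is None:
        k = min(8, n)
        step, _ = kabsch(ca[: k - 1], ca[1:k])  # screw mapping ca[i] -> ca[i+1]
        step_end, _ = kabsch(ca[n - k : -1], ca[n - k + 1 :])
        pre = step.inverse().apply(ca[0])
        post = step_end.apply(ca[-1])
        ca_ext = np.vstack([pre, ca, post])
    template = _ideal_residue_template()
    origins, rots = _ca_frames(ca_ext)
    coords = np.zeros((n, 5, 3))
    coords[:, _ATOM_INDEX["CA"], :] = ca
    for name in ("N", "C", "O", "CB"):
        coords[:, _ATOM_INDEX[name], :] = origins + rots @ template[name]
    return coords


# ---------------------------------------------------------------------------
# Crick curve and helix/bundle construction


def crick_ca_trace(params: CrickParams, t: np.ndarray | None = None) -> np.ndarray:
    """CA positions of the generalized Crick curve at residue indices ``t``."""
    if t is None:
        t = np.arange(params.length, dtype=float)
    t = np.asarray(t, dtype=float)
    r0 = params.supercoil_radius
    r1 = params.minor_radius
    d = params.rise_per_residue
    w0 = math.radians(params.supercoil_twist)
    w1 = math.radians(params.helical_twist)
    p0 = math.radians(params.supercoil_phase)
    p1 = math.radians(params.helical_phase)
    alpha = math.asin(r0 * w0 / d)
    c0, s0 = np.cos(w0 * t + p0), np.sin(w0 * t + p0)
    c1, s1 = np.cos(w1 * t + p1), np.sin(w1 * t + p1)
    ca_cos = math.cos(alpha)
    x = r0 * c0 + r1 * c0 * c1 - r1 * ca_cos * s0 * s1
    y = r0 * s0 + r1 * s0 * c1 + r1 * ca_cos * c0 * s1
    z = d * t * ca_cos - r1 * math.sin(alpha) * s1 + params.z_offset
    return np.column_stack([x, y, z])


def supercoil_track(params: CrickParams, t: np.ndarray | None = None) -> np.ndarray:
    """The helix-axis (supercoil) curve: the Crick curve with minor radius 0.

    Useful for handedness checks -- with ``omega0 < 0`` this track winds
    clockwise when viewed down the +z axis (a left-handed supercoil).
    """
    return crick_ca_trace(params.replace(minor_radius=1e-12), t)


def supercoil_local_phase(params: CrickParams, t: np.ndarray | None = None) -> np.ndarray:
    """Phase of each residue about its own helix axis, in the supercoil frame."""
    if t is None:
        t = np.arange(params.length, dtype=float)
    return (params.helical_twist * np.asarray(t, float) + params.helical_phase) % 360.0


def build_helix(
    params: CrickParams, chain_id: str = "A", res_name: str = "ALA"
) -> BackboneModel:
    """Build a single-chain helix backbone from Crick parameters."""
    t_ext = np.arange(-1, params.length + 1, dtype=float)
    ca_ext = crick_ca_trace(params, t_ext)
    coords = backbone_from_ca(ca_ext[1:-1], ca_ext)
    if params.inverted:
        centroid = ca_ext[1:-1].mean(axis=0)
        radial = np.array([centroid[0], centroid[1], 0.0])
        if np.linalg.norm(radial) < 1e-9:
            radial = np.array([1.0, 0.0, 0.0])
        flip = Transform.rotation_about_axis(radial, 180.0, point=centroid)
        coords = flip.apply(coords.reshape(-1, 3)).reshape(coords.shape)
    n = params.length
    return BackboneModel(
        np.full(n, chain_id, dtype="U4"),
        np.arange(1, n + 1),
        np.full(n, res_name, dtype="U3"),
        coords,
    )


def helix_axis_distance(a: CrickParams, b: CrickParams) -> float:
    """Distance between two helix axis tracks at equal z (law of cosines)."""
    dphi = math.radians(a.supercoil_phase - b.supercoil_phase)
    ra, rb = a.supercoil_radius, b.supercoil_radius
    return math.sqrt(max(ra * ra + rb * rb - 2 * ra * rb * math.cos(dphi), 0.0))


def assemble_bundle(spec: BundleSpec, res_name: str = "ALA") -> BackboneModel:
    """Assemble a multi-chain bundle; axis clashes are noted in metadata."""
    parts = [
        build_helix(h, chain_id=cid, res_name=res_name)
        for h, cid in zip(spec.helices, spec.chain_ids)
    ]
    model = BackboneModel.concatenate(parts)
    clashes = []
    for i in range(len(spec.helices)):
        for j in range(i + 1, len(spec.helices)):
            d = helix_axis_distance(spec.helices[i], spec.helices[j])
            if d < 6.0:
                clashes.append((spec.chain_ids[i], spec.chain_ids[j], round(d, 3)))
    if clashes:
        model.meta["axis_clashes"] = clashes
        warnings.warn(f"helix axes closer than 6 A: {clashes}", stacklevel=2)
    return model


# ---------------------------------------------------------------------------
# superposition


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[Transform, float]:
    """Least-squares proper rigid transform mapping point set ``p`` onto ``q``.

    Returns the transform and the minimized RMSD.  Reflections are excluded.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise GeometryError("point sets must have equal shapes")
    if len(p) < 3:
        raise GeometryError("need at least 3 points")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if np.linalg.matrix_rank(pc, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) selection")
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    tra = q.mean(axis=0) - rot @ p.mean(axis=0)
    diff = (p @ rot.T + tra) - q
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return Transform(rot, tra), rmsd


def superpose(
    model_a: BackboneModel,
    model_b: BackboneModel,
    atoms: Sequence[str] = ("CA",),
    selection_a: np.ndarray | None = None,
    selection_b: np.ndarray | None = None,
) -> tuple[Transform, float]:
    """Superpose ``model_b`` onto ``model_a`` over the selected atoms.

    Returns the proper rigid transform to apply to ``model_b`` and the
    minimized RMSD over the selection.
    """
    sel_a = np.ones(len(model_a), bool) if selection_a is None else selection_a
    sel_b = np.ones(len(model_b), bool) if selection_b is None else selection_b
    pa = np.concatenate([model_a.atom_coords(n)[sel_a] for n in atoms])
    pb = np.concatenate([model_b.atom_coords(n)[sel_b] for n in atoms])
    return kabsch(pb, pa)
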