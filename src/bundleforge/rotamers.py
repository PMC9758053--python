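"""Discrete sidechain rotamer placement for polar network design.

Sidechains are built from each residue's backbone frame (N, CA, CB) with
ideal internal coordinates and chi angles drawn from a coarse discrete
grid: staggered values for sp3 chis, {-90, 0, 90} for terminal sp2 chis and
a 30-degree grid for aromatic/imidazole ring chis.  An extra-rotamer mode
adds +/-20-degree sub-rotamers around each base chi value.  The allowed
types default to the polar residues plus the acidic Asp/Glu; Lys/Arg can be
enabled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from bundleforge.geometry import BackboneModel, place_atom

SP3 = "sp3"
SP2 = "sp2"
RING = "ring"

_SP3_GRID = (-60.0, 60.0, 180.0)
_SP2_GRID = (-90.0, 0.0, 90.0)
_RING_GRID = tuple(float(a) for a in range(-180, 180, 30))
_EXTRA_OFFSETS = (-20.0, 0.0, 20.0)

# atom build recipes: (name, (ref_a, ref_b, ref_c), bond, angle, dihedral)
# dihedral is ("chi", index, offset) or ("fixed", value); refs may be
# backbone N/CA/CB or previously placed sidechain atoms.
_SIDECHAINS: dict[str, dict] = {
    "SER": {
        "chis": (SP3,),
        "atoms": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 0, 0.0))],
        "donors": [("OG", "CB")],
        "acceptors": [("OG", "CB")],
    },
    "THR": {
        "chis": (SP3,),
        "atoms": [
            ("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 0, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 0, -120.0)),
        ],
        "donors": [("OG1", "CB")],
        "acceptors": [("OG1", "CB")],
    },
    "ASN": {
        "chis": (SP3, SP2),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 0, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 1, 0.0)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 1, 180.0)),
        ],
        "donors": [("ND2", "CG")],
        "acceptors": [("OD1", "CG")],
    },
    "ASP": {
        "chis": (SP3, SP2),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 0, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.5, ("chi", 1, 0.0)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.5, ("chi", 1, 180.0)),
        ],
        "donors": [],
        "acceptors": [("OD1", "CG"), ("OD2", "CG")],
    },
    "GLN": {
        "chis": (SP3, SP3, SP2),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 2, 0.0)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 2, 180.0)),
        ],
        "donors": [("NE2", "CD")],
        "acceptors": [("OE1", "CD")],
    },
    "GLU": {
        "chis": (SP3, SP3, SP2),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.5, ("chi", 2, 0.0)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.5, ("chi", 2, 180.0)),
        ],
        "donors": [],
        "acceptors": [("OE1", "CD"), ("OE2", "CD")],
    },
    "HIS": {
        "chis": (SP3, RING),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 0, 0.0)),
            ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 129.7, ("chi", 1, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.319, 109.3, ("fixed", 180.0)),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, ("fixed", 180.0)),
        ],
        "donors": [("ND1", "CG"), ("NE2", "CE1")],
        "acceptors": [("ND1", "CG"), ("NE2", "CE1")],
    },
    "TYR": {
        "chis": (SP3, RING),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.512, 113.9, ("chi", 0, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, ("chi", 1, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, ("fixed", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, ("fixed", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, ("fixed", 0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fixed", 180.0)),
        ],
        "donors": [("OH", "CZ")],
        "acceptors": [("OH", "CZ")],
    },
    "TRP": {
        "chis": (SP3, RING),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 0, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, ("chi", 1, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, ("fixed", 180.0)),
            ("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, ("fixed", 0.0)),
            ("CE3", ("NE1", "CE2", "CD2"), 1.398, 133.9, ("fixed", 180.0)),
            ("CZ2", ("CD1", "NE1", "CE2"), 1.394, 130.1, ("fixed", 180.0)),
            ("CZ3", ("CE2", "CD2", "CE3"), 1.382, 118.6, ("fixed", 180.0)),
            ("CH2", ("CD2", "CE3", "CZ3"), 1.368, 121.1, ("fixed", 0.0)),
        ],
        "donors": [("NE1", "CD1")],
        "acceptors": [],
    },
    "LYS": {
        "chis": (SP3, SP3, SP3, SP3),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 1, 0.0)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 2, 0.0)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 3, 0.0)),
        ],
        "donors": [("NZ", "CE")],
        "acceptors": [],
    },
    "ARG": {
        "chis": (SP3, SP3, SP3, SP2),
        "atoms": [
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 1, 0.0)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 2, 0.0)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 3, 0.0)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.3, ("fixed", 0.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.3, ("fixed", 180.0)),
        ],
        "donors": [("NE", "CZ"), ("NH1", "CZ"), ("NH2", "CZ")],
        "acceptors": [],
    },
}

#: polar residues plus acidic Asp/Glu; Lys/Arg available but off by default
DEFAULT_ALLOWED = ("SER", "THR", "ASN", "GLN", "HIS", "TYR", "TRP", "ASP", "GLU")
AROMATIC_NETWORK_TYPES = frozenset({"TYR", "TRP"})

CLASH_DISTANCE = 2.8  # A, hard-sphere heavy-atom clash proxy


class RotamerError(ValueError):
    """Unknown residue type or unusable position."""


@dataclass(frozen=True)
class RotamerPlacement:
    """One sidechain rotamer placed on a specific backbone position."""

    chain: str
    res_id: int
    res_type: str
    chis: tuple[float, ...]
    atom_names: tuple[str, ...]
    coords: np.ndarray = field(compare=False, hash=False)  # (n_atoms, 3)
    donors: tuple[tuple[str, str], ...]  # (atom, base-atom) pairs
    acceptors: tuple[tuple[str, str], ...]
    cb: np.ndarray = field(default=None, compare=False, hash=False)

    def atom(self, name: str) -> np.ndarray:
        if name == "CB":
            return self.cb
        return self.coords[self.atom_names.index(name)]

    @property
    def position(self) -> tuple[str, int]:
        return (self.chain, self.res_id)

    @property
    def polar_atoms(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(a for a, _ in self.donors + self.acceptors))


def chi_grids(res_type: str, extra: bool = False) -> list[tuple[float, ...]]:
    """Base (or extra-rotamer) chi grids per chi of ``res_type``."""
    try:
        kinds = _SIDECHAINS[res_type]["chis"]
    except KeyError:
        raise RotamerError(f"unknown residue type {res_type!r}") from None
    grids = []
    for kind in kinds:
        base = {SP3: _SP3_GRID, SP2: _SP2_GRID, RING: _RING_GRID}[kind]
        if extra and kind != RING:
            vals = tuple(
                ((b + off + 180.0) % 360.0) - 180.0
                for b in base
                for off in _EXTRA_OFFSETS
            )
        else:
            vals = base
        grids.append(vals)
    return grids


def _place_atom_batch(a, b, c, bond, angle_deg, dihedral_deg):
    """Vectorized NeRF placement; a/b/c are (m, 3), dihedral_deg is (m,)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d0 = -bond * np.cos(ang)
    d1 = bond * np.sin(ang) * np.cos(dih)
    d2 = bond * np.sin(ang) * np.sin(dih)
    return c + d0 * bc + d1[:, None] * m + d2[:, None] * n


def build_sidechain(
    n: np.ndarray, ca: np.ndarray, cb: np.ndarray, res_type: str, chis
) -> tuple[tuple[str, ...], np.ndarray]:
    """Place the heavy sidechain atoms beyond CB for one rotamer."""
    names, coords = build_sidechain_batch(
        n, ca, cb, res_type, np.asarray(chis, float)[None, :]
    )
    return names, coords[0]


def build_sidechain_batch(
    n: np.ndarray, ca: np.ndarray, cb: np.ndarray, res_type: str, chi_array
) -> tuple[tuple[str, ...], np.ndarray]:
    """Place sidechains for many chi combinations at once.

    ``chi_array`` has shape (m, n_chi); returns atom names and coordinates
    of shape (m, n_atoms, 3).
    """
    recipe = _SIDECHAINS[res_type]
    chi_array = np.asarray(chi_array, dtype=float)
    m = len(chi_array)
    placed = {
        "N": np.broadcast_to(n, (m, 3)),
        "CA": np.broadcast_to(ca, (m, 3)),
        "CB": np.broadcast_to(cb, (m, 3)),
    }
    names = []
    for name, refs, bond, angle, dih in recipe["atoms"]:
        if dih[0] == "chi":
            values = chi_array[:, dih[1]] + dih[2]
        else:
            values = np.full(m, dih[1])
        placed[name] = _place_atom_batch(
            placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, values
        )
        names.append(name)
    coords = np.stack([placed[nm] for nm in names], axis=1)
    return tuple(names), coords


def _backbone_tree(model: BackboneModel) -> tuple[cKDTree, np.ndarray]:
    coords = model.coords.reshape(-1, 3)
    owner = np.repeat(np.arange(len(model)), 5)
    return cKDTree(coords), owner


def enumerate_rotamers(
    model: BackboneModel,
    position: tuple[str, int],
    allowed_types=DEFAULT_ALLOWED,
    extra: bool = False,
    clash_check: bool = True,
    _backbone=None,
) -> list[RotamerPlacement]:
    """All clash-free rotamer placements of the allowed types at a position.

    ``extra`` switches on the +/-20-degree sub-rotamer grid.  Placements
    with any sidechain heavy atom within 2.8 A of another residue's
    backbone are discarded.
    """
    chain, res_id = position
    mask = (model.chain_ids == chain) & (model.res_ids == res_id)
    idx = np.flatnonzero(mask)
    if len(idx) != 1:
        raise RotamerError(f"position {position} not found uniquely")
    i = int(idx[0])
    n_xyz = model.coords[i, 0]
    ca_xyz = model.coords[i, 1]
    cb_xyz = model.coords[i, 4]
    tree, owner = _backbone_tree(model) if _backbone is None else _backbone
    out: list[RotamerPlacement] = []
    for res_type in allowed_types:
        if res_type not in _SIDECHAINS:
            raise RotamerError(f"unknown residue type {res_type!r}")
        recipe = _SIDECHAINS[res_type]
        combos = np.array(list(product(*chi_grids(res_type, extra=extra))))
        names, coords = build_sidechain_batch(n_xyz, ca_xyz, cb_xyz, res_type, combos)
        if clash_check:
            flat = coords.reshape(-1, 3)
            hits = tree.query_ball_point(flat, CLASH_DISTANCE)
            n_atoms = coords.shape[1]
            bad = np.zeros(len(combos), dtype=bool)
            for k, hit in enumerate(hits):
                if any(owner[j] != i for j in hit):
                    bad[k // n_atoms] = True
            keep = np.flatnonzero(~bad)
        else:
            keep = np.arange(len(combos))
        for k in keep:
            out.append(
                RotamerPlacement(
                    chain=str(chain),
                    res_id=int(res_id),
                    res_type=res_type,
                    chis=tuple(float(c) for c in combos[k]),
                    atom_names=names,
                    coords=coords[k],
                    donors=tuple(recipe["donors"]),
                    acceptors=tuple(recipe["acceptors"]),
                    cb=cb_xyz,
                )
            )
    return out


def placements_clash(a: RotamerPlacement, b: RotamerPlacement) -> bool:
    """Hard-sphere clash between two placements' sidechain heavy atoms."""
    d2 = np.sum((a.coords[:, None, :] - b.coords[None, :, :]) ** 2, axis=2)
    return bool((d2 < CLASH_DISTANCE**2).any())
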