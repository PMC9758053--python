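"""Geometric hydrogen-bond detection and Monte Carlo network search.

A hydrogen bond is scored purely geometrically on heavy atoms: the
donor-acceptor distance must fall in a configured window and the angles at
the donor (with the hydrogen placed implicitly at ideal geometry) and at
the acceptor must exceed configured cutoffs.  The Monte Carlo search seeds
a random polar rotamer at a searchable position and stochastically extends
it with hydrogen-bond-forming, clash-free placements until no extension is
possible; networks that span the required chains with enough residues are
retained and deduplicated by their position -> residue-type map.

Satisfaction accounting follows the buried-polar design rule: a network
passes only when every buried donor/acceptor heavy atom among its
sidechains participates in at least one hydrogen bond; atoms outside the
burial radius count as solvent-exposed and are satisfied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from bundleforge.geometry import BackboneModel
from bundleforge.register import SearchMask
from bundleforge.rotamers import (
    AROMATIC_NETWORK_TYPES,
    CLASH_DISTANCE,
    DEFAULT_ALLOWED,
    RotamerPlacement,
    enumerate_rotamers,
)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition on heavy atoms."""

    min_distance: float = 2.6  # A, donor-acceptor heavy atoms
    max_distance: float = 3.3
    min_donor_angle: float = 120.0  # deg at the donor (base-donor-acceptor)
    min_acceptor_angle: float = 90.0  # deg at the acceptor


@dataclass(frozen=True)
class HBond:
    donor_placement: int  # index into the placement list (-1 = backbone)
    donor_atom: str
    acceptor_placement: int
    acceptor_atom: str
    distance: float
    donor_angle: float
    acceptor_angle: float


@dataclass
class Network:
    """A connected set of rotamer placements joined by hydrogen bonds."""

    placements: list[RotamerPlacement]
    hbonds: list[HBond]
    chains: frozenset
    aromatic_count: int
    satisfaction: float | None = None

    def __len__(self) -> int:
        return len(self.placements)

    @property
    def residue_map(self) -> tuple:
        """Canonical (chain, res_id, type) key used for deduplication."""
        return tuple(
            sorted((p.chain, p.res_id, p.res_type) for p in self.placements)
        )

    @property
    def positions(self) -> dict:
        return {p.position: p.res_type for p in self.placements}


@dataclass(frozen=True)
class NetworkConstraints:
    """Per-network and cross-network acceptance rules."""

    min_residues: int = 3
    span_chains: frozenset | None = None  # None = all chains of the model
    networks_required: int = 3
    min_aromatics_total: int = 2  # Tyr/Trp across the selected networks


class SearchSetupError(ValueError):
    """Constraints impossible for the given mask/model."""


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    placements: list[RotamerPlacement],
    model: BackboneModel | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    include_backbone: bool = False,
) -> list[HBond]:
    """All donor/acceptor heavy-atom pairs meeting the geometric criteria.

    Pairs within one placement are skipped.  With ``include_backbone`` the
    model's backbone amide N (donor) and carbonyl O (acceptor) participate
    too, indexed as placement -1 with atom names ``N:<chain>:<res>`` /
    ``O:<chain>:<res>``.
    """
    donor_entries = []  # (placement_idx, atom_name, xyz, base_xyz)
    acceptor_entries = []
    for pi, p in enumerate(placements):
        for atom, base in p.donors:
            donor_entries.append((pi, atom, p.atom(atom), p.atom(base)))
        for atom, base in p.acceptors:
            acceptor_entries.append((pi, atom, p.atom(atom), p.atom(base)))
    if include_backbone and model is not None:
        for i in range(len(model)):
            tag = f"{model.chain_ids[i]}:{model.res_ids[i]}"
            acceptor_entries.append((-1, f"O:{tag}", model.coords[i, 3], model.coords[i, 2]))
            donor_entries.append((-1, f"N:{tag}", model.coords[i, 0], model.coords[i, 1]))
    if not donor_entries or not acceptor_entries:
        return []
    d_xyz = np.array([e[2] for e in donor_entries])
    d_base = np.array([e[3] for e in donor_entries])
    a_xyz = np.array([e[2] for e in acceptor_entries])
    a_base = np.array([e[3] for e in acceptor_entries])
    pairs = cKDTree(d_xyz).query_ball_tree(cKDTree(a_xyz), criteria.max_distance)
    di_idx = np.array([i for i, hits in enumerate(pairs) for _ in hits], dtype=int)
    ai_idx = np.array([j for hits in pairs for j in hits], dtype=int)
    if len(di_idx) == 0:
        return []
    # drop intra-placement and backbone-backbone pairs
    d_pl = np.array([e[0] for e in donor_entries])[di_idx]
    a_pl = np.array([e[0] for e in acceptor_entries])[ai_idx]
    keep = ~((d_pl == a_pl) & (d_pl >= 0)) & ~((d_pl == -1) & (a_pl == -1))
    di_idx, ai_idx = di_idx[keep], ai_idx[keep]
    if len(di_idx) == 0:
        return []
    dv = a_xyz[ai_idx] - d_xyz[di_idx]
    dist = np.linalg.norm(dv, axis=1)
    keep = dist >= criteria.min_distance

    def angles(base, center, other):
        v1 = base - center
        v2 = other - center
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    dang = angles(d_base[di_idx], d_xyz[di_idx], a_xyz[ai_idx])
    aang = angles(a_base[ai_idx], a_xyz[ai_idx], d_xyz[di_idx])
    keep &= (dang >= criteria.min_donor_angle) & (aang >= criteria.min_acceptor_angle)
    out: list[HBond] = []
    for k in np.flatnonzero(keep):
        di, ai = int(di_idx[k]), int(ai_idx[k])
        out.append(
            HBond(
                donor_entries[di][0],
                donor_entries[di][1],
                acceptor_entries[ai][0],
                acceptor_entries[ai][1],
                float(dist[k]),
                float(dang[k]),
                float(aang[k]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Monte Carlo search


@dataclass
class _SearchIndex:
    """Precomputed placement lists and adjacency for fast MC trials."""

    placements: list[RotamerPlacement]
    by_position: dict  # position -> list of placement indices
    hbond_partners: list  # idx -> set of idx
    clash_pairs: set  # packed int keys min(i,j)*n + max(i,j)

    @property
    def n_positions(self) -> int:
        return len(self.by_position)


def build_search_index(
    model: BackboneModel,
    positions: list[tuple[str, int]],
    allowed_types=DEFAULT_ALLOWED,
    criteria: HBondCriteria = HBondCriteria(),
    extra_rotamers: bool = True,
) -> _SearchIndex:
    """Enumerate rotamers at every searchable position and index pairwise
    hydrogen bonds and clashes between them."""
    from bundleforge.rotamers import _backbone_tree

    backbone = _backbone_tree(model)
    placements: list[RotamerPlacement] = []
    by_position: dict = {}
    for pos in positions:
        rots = enumerate_rotamers(
            model, pos, allowed_types, extra=extra_rotamers, _backbone=backbone
        )
        ids = list(range(len(placements), len(placements) + len(rots)))
        placements.extend(rots)
        by_position[pos] = ids
    hbonds = detect_hbonds(placements, model, criteria)
    partners = [set() for _ in placements]
    for hb in hbonds:
        if hb.donor_placement >= 0 and hb.acceptor_placement >= 0:
            partners[hb.donor_placement].add(hb.acceptor_placement)
            partners[hb.acceptor_placement].add(hb.donor_placement)
    # clash pairs via one KD-tree over every sidechain heavy atom
    clash_pairs: set = set()
    if len(placements) > 1:
        atoms = np.concatenate([p.coords for p in placements])
        owner = np.concatenate(
            [np.full(len(p.coords), i) for i, p in enumerate(placements)]
        )
        pos_ids = {pos: k for k, pos in enumerate(by_position)}
        pos_of = np.array([pos_ids[p.position] for p in placements])
        tree = cKDTree(atoms)
        raw = tree.query_pairs(CLASH_DISTANCE, output_type="ndarray")
        if len(raw):
            a = owner[raw[:, 0]]
            b = owner[raw[:, 1]]
            keep = pos_of[a] != pos_of[b]
            a, b = a[keep], b[keep]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            uniq = np.unique(lo.astype(np.int64) * len(placements) + hi)
            clash_pairs = set(uniq.tolist())
    return _SearchIndex(placements, by_position, partners, clash_pairs)


def mc_network_search(
    model: BackboneModel,
    mask: SearchMask | list[tuple[str, int]],
    constraints: NetworkConstraints = NetworkConstraints(),
    trials: int = 100_000,
    seed: int = 0,
    allowed_types=DEFAULT_ALLOWED,
    criteria: HBondCriteria = HBondCriteria(),
    extra_rotamers: bool = True,
    index: _SearchIndex | None = None,
) -> list[Network]:
    """Monte Carlo hydrogen-bond-network search over masked positions.

    Each trial seeds one random placement and extends it stochastically
    with bond-forming, clash-free placements until stuck.  Networks meeting
    the per-network constraints (size, chain span) are retained and
    deduplicated by their (position -> residue type) map.  Deterministic for
    a fixed seed; per-trial randomness comes from sub-seeds derived from
    ``(seed, trial)``, so a longer run reproduces and extends a shorter one.
    """
    positions = mask.positions() if isinstance(mask, SearchMask) else list(mask)
    if not positions:
        raise SearchSetupError("mask has no searchable positions")
    if trials < 1:
        raise SearchSetupError("trials must be >= 1")
    span = constraints.span_chains or frozenset(model.chains)
    if constraints.min_residues > len(positions):
        raise SearchSetupError("min_residues exceeds searchable position count")
    if not span <= {c for c, _ in positions}:
        raise SearchSetupError("required chains have no searchable positions")
    if index is None:
        index = build_search_index(
            model, positions, allowed_types, criteria, extra_rotamers
        )
    if not index.placements:
        return []
    networks: dict[tuple, Network] = {}
    n_pl = len(index.placements)
    for trial in range(trials):
        rng = np.random.default_rng([seed, trial])
        start = int(rng.integers(n_pl))
        members = [start]
        used_positions = {index.placements[start].position}
        while True:
            candidates = set()
            for m in members:
                candidates |= index.hbond_partners[m]
            candidates = [
                c
                for c in candidates
                if index.placements[c].position not in used_positions
                and all(
                    min(c, m) * n_pl + max(c, m) not in index.clash_pairs
                    for m in members
                )
            ]
            if not candidates:
                break
            pick = int(rng.choice(sorted(candidates)))
            members.append(pick)
            used_positions.add(index.placements[pick].position)
        chains = frozenset(index.placements[m].chain for m in members)
        if len(members) < constraints.min_residues or not span <= chains:
            continue
        chosen = [index.placements[m] for m in members]
        hbonds = detect_hbonds(chosen, model, criteria)
        net = Network(
            placements=chosen,
            hbonds=hbonds,
            chains=chains,
            aromatic_count=sum(
                1 for p in chosen if p.res_type in AROMATIC_NETWORK_TYPES
            ),
        )
        networks.setdefault(net.residue_map, net)
    return list(networks.values())


def select_network_sets(
    networks: list[Network], constraints: NetworkConstraints
) -> list[tuple[Network, ...]]:
    """Combinations of position-disjoint networks meeting the cross-network
    constraints (count and total Tyr/Trp)."""
    out = []
    for combo in combinations(networks, constraints.networks_required):
        positions: set = set()
        ok = True
        for net in combo:
            pos = set(net.positions)
            if positions & pos:
                ok = False
                break
            positions |= pos
        if not ok:
            continue
        if sum(n.aromatic_count for n in combo) < constraints.min_aromatics_total:
            continue
        out.append(combo)
    return out


def network_satisfaction(
    network: Network,
    model: BackboneModel,
    criteria: HBondCriteria = HBondCriteria(),
    burial_radius: float | None = None,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
    include_backbone: bool = True,
) -> tuple[float, bool]:
    """Fraction of satisfied polar heavy atoms and the buried-pass verdict.

    An atom is satisfied when it takes part in at least one detected
    hydrogen bond (side chain or backbone) or lies outside the burial
    radius (a distance-from-axis proxy for solvent exposure).  The network
    passes only if every buried polar atom is satisfied.  ``burial_radius``
    defaults to the model's maximal CA axis distance plus 3 A.
    """
    axis_point = np.asarray(axis_point, float)
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    if burial_radius is None:
        rel = model.ca - axis_point
        radial = rel - np.outer(rel @ axis_dir, axis_dir)
        burial_radius = float(np.linalg.norm(radial, axis=1).max()) + 3.0
    hbonds = detect_hbonds(
        network.placements, model, criteria, include_backbone=include_backbone
    )
    bonded = set()
    for hb in hbonds:
        if hb.donor_placement >= 0:
            bonded.add((hb.donor_placement, hb.donor_atom))
        if hb.acceptor_placement >= 0:
            bonded.add((hb.acceptor_placement, hb.acceptor_atom))
    total = 0
    satisfied = 0
    buried_ok = True
    for pi, p in enumerate(network.placements):
        for atom in p.polar_atoms:
            total += 1
            xyz = p.atom(atom)
            rel = xyz - axis_point
            radial = rel - (rel @ axis_dir) * axis_dir
            buried = float(np.linalg.norm(radial)) < burial_radius
            ok = (pi, atom) in bonded or not buried
            if ok:
                satisfied += 1
            elif buried:
                buried_ok = False
    fraction = satisfied / total if total else 1.0
    return fraction, buried_ok
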