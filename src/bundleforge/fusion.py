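"""Rigid helical splice fusion and cyclic ring closure.

Two building blocks are fused by superposing an overlapping window of
helical residues at their termini (the donor's C-terminal window onto the
acceptor's N-terminal window), deleting up to a configured number of
residues from each side and keeping the lowest-RMSD overlap.  Repeated
junctions compose into a propagation transform; applying it n times and
measuring how far the probe structure lands from its start gives the ring
closure error (close_err).  Candidate rings are filtered on chain length,
an inter-copy backbone clash count (the score0 analogue) and close_err.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from bundleforge.geometry import (
    BackboneModel,
    GeometryError,
    Transform,
    kabsch,
)


class FusionError(ValueError):
    """No admissible splice between the given blocks."""


@dataclass(frozen=True)
class SpliceSite:
    """Helical residue window available for splicing at one terminus."""

    chain: str
    terminus: str  # "N" | "C"
    window: int = 14  # residues available inward from the terminus

    def __post_init__(self) -> None:
        if self.terminus not in ("N", "C"):
            raise FusionError("terminus must be 'N' or 'C'")
        if self.window < 1:
            raise FusionError("window must be positive")


@dataclass(frozen=True)
class SpliceLimits:
    """Deletion and overlap limits for a junction search."""

    max_delete_donor: int = 7  # heterotrimer side: up to one heptad
    max_delete_acceptor: int = 14  # repeat-protein side: up to one repeat
    min_overlap: int = 8  # > one helical turn


@dataclass
class JunctionSolution:
    """A scored rigid splice between a donor and an acceptor block."""

    overlap_rmsd: float
    overlap_len: int
    deleted_donor: int
    deleted_acceptor: int
    transform: Transform  # maps acceptor coordinates into the donor frame
    fused: BackboneModel


def _chain_ca(model: BackboneModel, chain: str) -> np.ndarray:
    ca = model.chain_slice(chain).ca
    if len(ca) == 0:
        raise FusionError(f"chain {chain!r} missing")
    return ca


def enumerate_splices(
    donor: BackboneModel,
    donor_site: SpliceSite,
    acceptor: BackboneModel,
    acceptor_site: SpliceSite,
    limits: SpliceLimits = SpliceLimits(),
) -> list[JunctionSolution]:
    """All admissible overlap splices, sorted by overlap RMSD ascending.

    The donor contributes its chain up to the junction; the overlap region
    and everything downstream take the acceptor's geometry after
    superposing the acceptor's window onto the donor's.
    """
    if donor_site.terminus == acceptor_site.terminus:
        raise FusionError("need one C terminus and one N terminus")
    if donor_site.terminus == "N":
        # normalize: donor always provides the C-terminal side
        sols = enumerate_splices(acceptor, acceptor_site, donor, donor_site, limits)
        return sols
    d_model = donor.chain_slice(donor_site.chain)
    a_model = acceptor.chain_slice(acceptor_site.chain)
    solutions: list[JunctionSolution] = []
    for del_d in range(limits.max_delete_donor + 1):
        n_d = len(d_model) - del_d
        for del_a in range(limits.max_delete_acceptor + 1):
            n_a = len(a_model) - del_a
            max_ov = min(donor_site.window - del_d, acceptor_site.window - del_a, n_d, n_a)
            for overlap in range(limits.min_overlap, max_ov + 1):
                d_idx = np.arange(n_d - overlap, n_d)
                a_idx = np.arange(del_a, del_a + overlap)
                try:
                    transform, rmsd = kabsch(
                        a_model.ca[a_idx], d_model.ca[d_idx]
                    )
                except GeometryError:
                    continue
                fused = _fuse(d_model, a_model, d_idx, a_idx, transform, donor_site.chain)
                solutions.append(
                    JunctionSolution(rmsd, overlap, del_d, del_a, transform, fused)
                )
    if not solutions:
        raise FusionError("no overlap satisfies the limits")
    solutions.sort(key=lambda s: (s.overlap_rmsd, -s.overlap_len))
    return solutions


def _fuse(d_model, a_model, d_idx, a_idx, transform, chain_id) -> BackboneModel:
    """Donor residues before the overlap + transformed acceptor chain."""
    keep_d = np.arange(len(d_model)) < d_idx[0]
    keep_a = np.arange(len(a_model)) >= a_idx[0]
    a_moved = a_model.transformed(transform)
    n_total = int(keep_d.sum() + keep_a.sum())
    coords = np.concatenate([d_model.coords[keep_d], a_moved.coords[keep_a]])
    res_names = np.concatenate([d_model.res_names[keep_d], a_moved.res_names[keep_a]])
    return BackboneModel(
        np.full(n_total, chain_id, dtype="U4"),
        np.arange(1, n_total + 1),
        res_names,
        coords,
    )


# ---------------------------------------------------------------------------
# cyclic closure


def ring_closure_error(
    unit_transform: Transform, n: int, probe: BackboneModel
) -> float:
    """RMSD between the probe and the probe moved by the n-fold transform.

    Zero iff the transform composed n times is the identity over the probe
    span; a pure axial offset of delta per step accumulates to n * delta.
    """
    if n < 2:
        raise FusionError("cyclic order n must be >= 2")
    ca = probe.ca
    if len(ca) == 0:
        raise FusionError("empty probe")
    moved = unit_transform.power(n).apply(ca)
    return float(np.sqrt(((moved - ca) ** 2).sum(axis=1).mean()))


@dataclass(frozen=True)
class RingThresholds:
    """Acceptance filters mirroring the chain_len / score0 / close_err triple."""

    max_close_err: float = 1.0  # A
    max_clashes: int = 0  # inter-copy backbone heavy-atom pairs < 3.0 A
    max_chain_len: int = 10_000  # residues, per chain of the asymmetric unit


@dataclass
class RingSolution:
    """A propagated cyclic assembly and its filter scores."""

    unit: BackboneModel
    transform: Transform
    symmetry: int
    close_err: float
    clash_count: int
    chain_lengths: dict
    accepted: bool
    rejection_reasons: list = field(default_factory=list)
    ring: BackboneModel | None = None


CLASH_CUTOFF = 3.0  # A, inter-copy backbone heavy atoms


def build_ring(
    unit: BackboneModel,
    propagation: Transform,
    n: int,
    thresholds: RingThresholds = RingThresholds(),
) -> RingSolution:
    """Propagate ``n`` copies of the asymmetric unit and apply the filters.

    The full ring model is emitted only for accepted solutions; rejected
    candidates return a RingSolution with the failing filters listed.
    """
    close_err = ring_closure_error(propagation, n, unit)
    copies = [unit]
    current = Transform.identity()
    for _ in range(n - 1):
        current = propagation.compose(current)
        copies.append(unit.transformed(current))
    atoms = [c.coords[:, :4, :].reshape(-1, 3) for c in copies]  # N, CA, C, O
    clash_count = 0
    trees = [cKDTree(a) for a in atoms]
    for i in range(n):
        for j in range(i + 1, n):
            clash_count += trees[i].count_neighbors(trees[j], CLASH_CUTOFF)
    chain_lengths = {c: int(unit.chain_mask(c).sum()) for c in unit.chains}
    reasons = []
    if close_err > thresholds.max_close_err:
        reasons.append(f"close_err {close_err:.3f} > {thresholds.max_close_err}")
    if clash_count > thresholds.max_clashes:
        reasons.append(f"score0 {clash_count} > {thresholds.max_clashes}")
    if max(chain_lengths.values()) > thresholds.max_chain_len:
        reasons.append("chain_len over limit")
    accepted = not reasons
    ring = None
    if accepted:
        relabeled = []
        for k, c in enumerate(copies):
            cc = c.copy()
            cc.chain_ids = np.array(
                [f"{cid}{k}" if k else str(cid) for cid in cc.chain_ids], dtype="U4"
            )
            relabeled.append(cc)
        ring = BackboneModel.concatenate(relabeled)
    return RingSolution(
        unit, propagation, n, close_err, int(clash_count), chain_lengths,
        accepted, reasons, ring,
    )
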