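"""Off-target species bookkeeping, chain trimming and hairpin loop logic.

Designing an obligate ABC heterotrimer is a negative-design problem: every
alternative chain composition (monomers, homo- and hetero-dimers, non-ABC
trimers, ...) must be disfavored.  ``enumerate_species`` lists those
alternatives as unordered multisets.  Two listing conventions are
supported: ``full`` counts every multiset up to the maximum assembly size,
while ``paper-trimer`` additionally omits homotypic two-chain species, the
convention under which a three-chain system has 15 alternatives while a
two-chain system has 4 (A, B, AA, BB).

Chain trimming (whole heptads off one end) staggers the three chain
lengths; hairpin pairing closes a six-helix bundle into three helix-loop-
helix chains, clockwise (A-D; B-E; C-F) or counterclockwise (A-F; B-E;
C-D); loop feasibility checks whether 2-5 residue loops can span the
terminus gaps, allowing up to three residues to be deleted or two added at
each terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from bundleforge.geometry import BackboneModel


class TopologyError(ValueError):
    """Invalid species/pairing/trim request."""


# ---------------------------------------------------------------------------
# species enumeration


@dataclass(frozen=True)
class SpeciesSet:
    """Alternative (off-target) species as sorted composition strings."""

    alphabet: tuple[str, ...]
    max_size: int
    target: str | None
    convention: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def enumerate_species(
    alphabet,
    max_size: int,
    target: str | None = None,
    convention: str = "full",
) -> SpeciesSet:
    """All alternative multiset compositions of 1..max_size chains.

    The target composition is excluded.  ``convention="paper-trimer"``
    additionally excludes homotypic dimers (AA, BB, CC), matching the
    published 15-species listing for the ABC trimer.
    """
    alphabet = tuple(alphabet)
    if not alphabet:
        raise TopologyError("empty chain alphabet")
    if max_size < 1:
        raise TopologyError("max_size must be >= 1")
    if convention not in ("full", "paper-trimer"):
        raise TopologyError(f"unknown convention {convention!r}")
    target_key = "".join(sorted(target)) if target else None
    if target_key and len(target_key) > max_size:
        raise TopologyError("target larger than max assembly size")
    members = []
    for size in range(1, max_size + 1):
        for combo in combinations_with_replacement(alphabet, size):
            key = "".join(combo)
            if key == target_key:
                continue
            if (
                convention == "paper-trimer"
                and size == 2
                and combo[0] == combo[1]
            ):
                continue
            members.append(key)
    return SpeciesSet(alphabet, max_size, target_key, convention, tuple(members))


# ---------------------------------------------------------------------------
# chain trimming


def trim_chains(
    model: BackboneModel,
    heptad_trims: dict,
    end: str = "C",
) -> BackboneModel:
    """Remove whole heptads from one end of selected chains.

    ``heptad_trims`` maps chain id -> number of heptads to remove; ``end``
    is "N" or "C" (default C: the terminus distal to the shared interface).
    Residues are renumbered from 1; register annotation is preserved.
    """
    if end not in ("N", "C"):
        raise TopologyError("end must be 'N' or 'C'")
    keep = np.ones(len(model), dtype=bool)
    for chain, n_heptads in heptad_trims.items():
        if n_heptads < 0 or n_heptads != int(n_heptads):
            raise TopologyError("trims must be whole non-negative heptads")
        n_res = int(n_heptads) * 7
        mask = model.chain_mask(chain)
        total = int(mask.sum())
        if total == 0:
            raise TopologyError(f"chain {chain!r} not in model")
        if total - n_res < 7:
            raise TopologyError(
                f"trimming {n_heptads} heptads leaves chain {chain} "
                f"shorter than one heptad"
            )
        idx = np.flatnonzero(mask)
        drop = idx[-n_res:] if end == "C" and n_res else idx[:n_res]
        keep[drop] = False
    out = BackboneModel(
        model.chain_ids[keep],
        model.res_ids[keep],
        model.res_names[keep],
        model.coords[keep],
        None if model.register is None else model.register[keep],
        dict(model.meta),
    )
    for chain in out.chains:
        mask = out.chain_mask(chain)
        out.res_ids[mask] = np.arange(1, int(mask.sum()) + 1)
    return out


# ---------------------------------------------------------------------------
# hairpin pairings


@dataclass(frozen=True)
class PairingScheme:
    """Perfect matching of inner to outer helices for hairpin closure."""

    pairs: tuple[tuple[str, str], ...]
    direction: str  # "clockwise" | "counterclockwise"
    loop_side: str  # "same-side" | "opposing-ends"


def hairpin_pairings(
    direction: str,
    loop_side: str = "same-side",
    inner=("A", "B", "C"),
    outer=("D", "E", "F"),
) -> PairingScheme:
    """Inner-outer helix pairing for closing a six-helix bundle.

    Clockwise pairs (A-D; B-E; C-F); counterclockwise pairs (A-F; B-E;
    C-D).  ``loop_side`` records whether loops all face the same direction
    or sit at opposing terminal ends.
    """
    inner = tuple(inner)
    outer = tuple(outer)
    if direction == "clockwise":
        pairs = tuple(zip(inner, outer))
    elif direction == "counterclockwise":
        pairs = tuple(zip(inner, (outer[2], outer[1], outer[0])))
    else:
        raise TopologyError(f"unknown direction {direction!r}")
    if loop_side not in ("same-side", "opposing-ends"):
        raise TopologyError(f"unknown loop side {loop_side!r}")
    return PairingScheme(pairs, direction, loop_side)


# ---------------------------------------------------------------------------
# loop feasibility


def loop_span_limit(loop_len: int, per_residue: float = 3.3) -> float:
    """Maximum CA-CA gap a loop of ``loop_len`` residues can bridge (A)."""
    return per_residue * (loop_len + 1)


@dataclass(frozen=True)
class LoopOption:
    """One candidate closure of a helix pair."""

    chain_a: str
    chain_b: str
    end_a: str  # terminus used on chain a ("N" | "C")
    end_b: str
    trim_a: int  # residues removed (-) / added (+) at the terminus
    trim_b: int
    loop_len: int
    gap: float  # A between the loop anchor CAs
    feasible: bool


def loop_feasibility(
    model: BackboneModel,
    scheme: PairingScheme,
    loop_lengths=(2, 3, 4, 5),
    end_adjust=(-3, -2, -1, 0, 1, 2),
    per_residue: float = 3.3,
) -> dict:
    """Best loop-closure option per helix pair of a pairing scheme.

    For every pair the loop joins the C terminus of one helix to the N
    terminus of the other (both orders tried).  End adjustments delete up
    to three or extend up to two residues before measuring the anchor gap;
    extensions project along the terminal CA-CA direction.  A loop of n
    residues is feasible when the gap is at most ``per_residue * (n+1)``.
    Returns ``{(chain_a, chain_b): best LoopOption or None}``.
    """
    report: dict = {}
    for a, b in scheme.pairs:
        best: LoopOption | None = None
        for end_a, end_b in (("C", "N"), ("N", "C")):
            for trim_a in end_adjust:
                for trim_b in end_adjust:
                    pa = _terminus_ca(model, a, end_a, trim_a)
                    pb = _terminus_ca(model, b, end_b, trim_b)
                    if pa is None or pb is None:
                        continue
                    gap = float(np.linalg.norm(pa - pb))
                    for n in sorted(loop_lengths):
                        ok = gap <= loop_span_limit(n, per_residue)
                        opt = LoopOption(
                            a, b, end_a, end_b, trim_a, trim_b, n, gap, ok
                        )
                        if ok and (best is None or not best.feasible or _rank(opt) < _rank(best)):
                            best = opt
                        elif best is None:
                            best = opt
        report[(a, b)] = best
    return report


def _rank(opt: LoopOption) -> tuple:
    # prefer short loops and small end modifications
    return (opt.loop_len, abs(opt.trim_a) + abs(opt.trim_b), opt.gap)


def _terminus_ca(model: BackboneModel, chain: str, end: str, adjust: int):
    """Anchor CA after trimming (adjust<0) or extending (adjust>0) an end."""
    ca = model.chain_slice(chain).ca
    if len(ca) < 5 + abs(adjust):
        return None
    if end == "C":
        if adjust <= 0:
            return ca[len(ca) - 1 + adjust]
        step = ca[-1] - ca[-2]
        return ca[-1] + adjust * step
    if adjust <= 0:
        return ca[-adjust]
    step = ca[0] - ca[1]
    return ca[0] + adjust * step
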