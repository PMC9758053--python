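"""Heptad register assignment, N/P search masks and rule-based layer design.

Coiled-coil sequences repeat with a seven-residue (heptad) period whose
positions are lettered a-g; a and d (and, at trimeric interfaces, g) point
into the bundle core.  The register of a backbone is found geometrically:
the cyclic letter offset is chosen so that 'a' positions have CA->CB
vectors pointing most directly at the bundle axis.

Hydrogen-bond-network searches operate only inside designated polar (P)
heptads of an N/P pattern; the remaining nonpolar (N) heptads are left
fully hydrophobic to clamp the networks in place.  Layer design assigns
amino acids by burial class (core / boundary / surface) with a minimum of
two phenylalanines in the core, never touching network positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from bundleforge.geometry import BackboneModel

HEPTAD_LETTERS = "abcdefg"

CORE_ALPHABET = ("ALA", "ILE", "LEU", "VAL", "PHE", "MET", "TRP")
SURFACE_ALPHABET = ("GLU", "LYS", "ARG", "ASP", "GLN", "ASN", "SER", "THR")
BOUNDARY_ALPHABET = tuple(
    sorted((set(CORE_ALPHABET) | set(SURFACE_ALPHABET)) - {"TRP"})
)


class RegisterError(ValueError):
    """Input chain is unsuitable for register assignment."""


@dataclass
class RegisterAnnotation:
    """Per-residue heptad letters for every chain of a model."""

    chain_ids: np.ndarray  # (n,)
    res_ids: np.ndarray  # (n,)
    letters: np.ndarray  # (n,) single chars a-g
    heptad_index: np.ndarray  # (n,) position-block index i // 7 within chain
    core_facing: np.ndarray  # (n,) bool
    core_letters: frozenset = frozenset({"a", "d", "g"})

    def chain_letters(self, chain: str) -> str:
        return "".join(self.letters[self.chain_ids == chain])

    def n_heptads(self, chain: str) -> int:
        n = int((self.chain_ids == chain).sum())
        return -(-n // 7)  # ceil


@dataclass
class SearchMask:
    """Per-residue searchable flags derived from an N/P heptad pattern."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    heptad_polarity: dict  # (chain, heptad_index) -> 'N' | 'P'
    searchable: np.ndarray  # (n,) bool

    def positions(self) -> list[tuple[str, int]]:
        """Searchable (chain, residue-id) pairs in model order."""
        return [
            (str(c), int(r))
            for c, r, s in zip(self.chain_ids, self.res_ids, self.searchable)
            if s
        ]


def _axis_inwardness(model: BackboneModel, axis_point, axis_dir) -> np.ndarray:
    """cos(angle) between CA->CB and CA->axis-foot, per residue."""
    axis_point = np.asarray(axis_point, float)
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    ca = model.ca
    cb = model.atom_coords("CB")
    rel = ca - axis_point
    foot = axis_point + np.outer(rel @ axis_dir, axis_dir)
    inward = foot - ca
    inorm = np.linalg.norm(inward, axis=1)
    inorm[inorm < 1e-9] = 1.0
    cbdir = cb - ca
    cbnorm = np.linalg.norm(cbdir, axis=1)
    cbnorm[cbnorm < 1e-9] = 1.0
    return np.sum(inward * cbdir, axis=1) / (inorm * cbnorm)


def assign_register(
    model: BackboneModel,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
    include_g_core: bool = True,
    core_angle_deg: float = 60.0,
) -> RegisterAnnotation:
    """Assign heptad letters per chain from CB orientation about the axis.

    For each chain the cyclic offset placing 'a' on the most inward-pointing
    position class is selected; letters then advance cyclically with residue
    index.  Core-facing letters are {a, d} plus g when ``include_g_core``
    (the trimer-interface convention).  A residue is additionally required
    to point within ``core_angle_deg`` of the axis for its core flag.
    """
    inward = _axis_inwardness(model, axis_point, axis_dir)
    letters = np.empty(len(model), dtype="U1")
    heptads = np.zeros(len(model), dtype=int)
    core_letters = frozenset({"a", "d"} | ({"g"} if include_g_core else set()))
    cos_cut = np.cos(np.radians(core_angle_deg))
    for chain in model.chains:
        mask = model.chain_mask(chain)
        idx = np.flatnonzero(mask)
        if len(idx) < 7:
            raise RegisterError(f"chain {chain} shorter than one heptad")
        scores = inward[idx]
        # offset whose positions {o, o+7, ...} point most inward becomes 'a'
        best = max(range(7), key=lambda o: scores[o::7].mean())
        pos = np.arange(len(idx))
        letters[idx] = np.array(list(HEPTAD_LETTERS))[(pos - best) % 7]
        heptads[idx] = pos // 7
    is_core_letter = np.isin(letters, sorted(core_letters))
    core = is_core_letter & (inward > cos_cut)
    return RegisterAnnotation(
        model.chain_ids.copy(),
        model.res_ids.copy(),
        letters,
        heptads,
        core,
        frozenset(core_letters),
    )


def build_search_mask(annotation: RegisterAnnotation, pattern: str) -> SearchMask:
    """Center an N/P heptad pattern on each chain and mark searchable residues.

    Only residues inside P heptads at core-facing letters are searchable.
    Patterns shorter than the chain are centered; ties break toward the
    N terminus.
    """
    pattern = pattern.upper()
    if set(pattern) - {"N", "P"}:
        raise RegisterError("pattern must contain only N and P")
    chains: list[str] = []
    for c in annotation.chain_ids:
        if c not in chains:
            chains.append(str(c))
    polarity: dict = {}
    searchable = np.zeros(len(annotation.chain_ids), dtype=bool)
    for chain in chains:
        mask = annotation.chain_ids == chain
        n_hept = annotation.n_heptads(chain)
        if len(pattern) > n_hept:
            raise RegisterError(
                f"pattern of {len(pattern)} heptads exceeds chain {chain} "
                f"({n_hept} heptads)"
            )
        start = (n_hept - len(pattern)) // 2
        for h in range(n_hept):
            pol = pattern[h - start] if start <= h < start + len(pattern) else "N"
            polarity[(chain, h)] = pol
        idx = np.flatnonzero(mask)
        for local, i in enumerate(idx):
            h = int(annotation.heptad_index[i])
            if polarity[(chain, h)] == "P" and annotation.core_facing[i]:
                searchable[i] = True
    return SearchMask(
        annotation.chain_ids.copy(), annotation.res_ids.copy(), polarity, searchable
    )


def layer_sequence(
    model: BackboneModel,
    annotation: RegisterAnnotation,
    network_positions: dict | None = None,
    min_phe: int = 2,
) -> np.ndarray:
    """Rule-based per-residue amino-acid assignment by burial layer.

    Network positions (``{(chain, res_id): three-letter type}``) are kept
    untouched and always win over layer rules (a conflict emits a warning).
    Core-facing letters get nonpolar residues with at least ``min_phe``
    phenylalanines per design; surface letters (b, c, f) alternate Glu/Lys;
    the remaining boundary letters get Ala.
    """
    network_positions = network_positions or {}
    seq = np.empty(len(model), dtype="U3")
    net_keys = {(str(c), int(r)) for c, r in network_positions}
    core_sites: list[int] = []
    for i, (chain, res_id) in enumerate(zip(model.chain_ids, model.res_ids)):
        letter = annotation.letters[i]
        key = (str(chain), int(res_id))
        if key in net_keys:
            seq[i] = network_positions[key]
            if letter in annotation.core_letters:
                warnings.warn(
                    f"network position {key} overrides nonpolar core rule",
                    stacklevel=2,
                )
            continue
        if letter in annotation.core_letters:
            seq[i] = "LEU"
            core_sites.append(i)
        elif letter in ("b", "c", "f"):
            seq[i] = "GLU" if int(res_id) % 2 else "LYS"
        else:
            seq[i] = "ALA"
    # enforce the minimum phenylalanine count over non-network core sites
    n_phe = int((seq == "PHE").sum())
    if core_sites and n_phe < min_phe:
        mid = len(model) / 2.0
        central = sorted(core_sites, key=lambda i: abs(i - mid))
        for i in central[: min_phe - n_phe]:
            seq[i] = "PHE"
    return seq
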