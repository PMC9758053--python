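"""Deterministic generation of synthetic test inputs.

Every fixture is generated programmatically and self-verified at build
time: the manifest's claims (a planted hydrogen-bond triad, an exact
closure transform, splice window lengths) are re-checked with the same
module operations the tests exercise, so a fixture cannot silently drift
away from its advertised ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bundleforge.geometry import (
    BackboneModel,
    BundleSpec,
    CrickParams,
    Transform,
    assemble_bundle,
    backbone_from_ca,
    crick_ca_trace,
)
from bundleforge.hbnet import HBondCriteria, build_search_index, detect_hbonds
from bundleforge.register import assign_register, build_search_mask


class FixtureError(ValueError):
    """Unknown fixture kind or failed self-verification."""


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    params: tuple = ()  # optional (key, value) overrides


@dataclass
class Fixture:
    kind: str
    model: BackboneModel
    manifest: dict = field(default_factory=dict)
    extra_models: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> Fixture:
    """Build (and optionally write) the named fixture."""
    builders = {
        "planted-triad": planted_triad,
        "c3-wedge": c3_wedge,
        "toy-dhr": toy_dhr,
        "ideal-cc": ideal_coiled_coil,
    }
    try:
        builder = builders[spec.kind]
    except KeyError:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}") from None
    fixture = builder(seed=spec.seed, **dict(spec.params))
    if outdir is not None:
        from bundleforge.pdbio import write_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_model(fixture.model, outdir / f"{spec.kind}.pdb")
        for name, model in fixture.extra_models.items():
            write_model(model, outdir / f"{spec.kind}-{name}.pdb")
        with open(outdir / f"{spec.kind}.json", "w") as fh:
            json.dump(fixture.manifest, fh, indent=2, default=str)
    return fixture


def ideal_coiled_coil(
    seed: int = 0, length: int = 77, radius: float = 7.0, dphi1: float = 0.0
) -> Fixture:
    """Parallel C3 coiled-coil trimer with identical per-chain parameters."""
    spec = BundleSpec(
        tuple(
            CrickParams(
                supercoil_radius=radius,
                supercoil_phase=p,
                helical_phase=dphi1,
                length=length,
            )
            for p in (0.0, 120.0, 240.0)
        ),
        ("A", "B", "C"),
    )
    model = assemble_bundle(spec)
    return Fixture(
        "ideal-cc",
        model,
        {"length": length, "radius": radius, "dphi1": dphi1, "chains": ["A", "B", "C"]},
    )


def planted_triad(
    seed: int = 0,
    length: int = 35,
    radius: float = 7.0,
    pattern: str = "NPPPN",
    allowed_types: tuple = ("SER", "THR", "ASN"),
) -> Fixture:
    """C3 trimer backbone hosting a verified Ser/Thr/Asn hydrogen-bond triad.

    The searchable positions of the central polar heptads are enumerated
    with the standard rotamer grids (extra-rotamer mode) and the first
    clash-free, three-chain connected triad found in deterministic order is
    recorded in the manifest.  Its hydrogen bonds are re-verified with
    ``detect_hbonds`` before the fixture is accepted.
    """
    base = ideal_coiled_coil(seed=seed, length=length, radius=radius)
    model = base.model
    annotation = assign_register(model)
    mask = build_search_mask(annotation, pattern)
    positions = mask.positions()
    index = build_search_index(
        model, positions, allowed_types=allowed_types, extra_rotamers=True
    )
    triad = _find_triad(index)
    if triad is None:
        raise FixtureError("no connected three-chain triad found; bad geometry")
    placements = [index.placements[i] for i in triad]
    hbonds = detect_hbonds(placements, model, HBondCriteria())
    chains = {p.chain for p in placements}
    if len(chains) != 3 or len(hbonds) < 2:
        raise FixtureError("triad failed hydrogen-bond re-verification")
    manifest = {
        "length": length,
        "radius": radius,
        "pattern": pattern,
        "triad": [
            {
                "chain": p.chain,
                "res_id": p.res_id,
                "res_type": p.res_type,
                "chis": list(p.chis),
            }
            for p in placements
        ],
        "n_hbonds": len(hbonds),
        "searchable_positions": [list(p) for p in positions],
    }
    fx = Fixture("planted-triad", model, manifest)
    fx.manifest["allowed_types"] = list(allowed_types)
    return fx


def _find_triad(index):
    """First three-placement set spanning chains A, B, C, connected by
    hydrogen bonds and mutually clash-free, in deterministic order."""
    n_pl = len(index.placements)
    by_chain: dict = {}
    for i, p in enumerate(index.placements):
        by_chain.setdefault(p.chain, []).append(i)
    chains = sorted(by_chain)
    if len(chains) < 3:
        return None
    a_ids, b_ids, c_ids = (by_chain[c] for c in chains[:3])
    clash = index.clash_pairs

    def ok(i, j):
        return (min(i, j) * n_pl + max(i, j)) not in clash

    for b in b_ids:
        partners = index.hbond_partners[b]
        for a in a_ids:
            if a not in partners:
                continue
            for c in c_ids:
                # connected via b, or a chain a-c bond closing a path
                connected = c in partners or c in index.hbond_partners[a]
                if connected and ok(a, b) and ok(b, c) and ok(a, c):
                    return (a, b, c)
    return None


def c3_wedge(seed: int = 0, radius: float = 12.0, helix_len: int = 18) -> Fixture:
    """Two-helix wedge whose junction transform is an exact 120-deg rotation.

    The unit holds two straight helices inside one 120-degree sector;
    propagating it three times closes a C3 ring with zero closure error and
    no inter-copy clashes.
    """
    t_ext = np.arange(-1, helix_len + 1, dtype=float)
    base = CrickParams(
        supercoil_radius=0.0, supercoil_twist=0.0, length=helix_len
    )
    ca = crick_ca_trace(base, t_ext)

    def place(angle_deg: float) -> np.ndarray:
        shift = np.array(
            [radius * np.cos(np.radians(angle_deg)), radius * np.sin(np.radians(angle_deg)), 0.0]
        )
        return backbone_from_ca(ca[1:-1] + shift, ca + shift)

    coords = np.concatenate([place(0.0), place(60.0)])
    n = helix_len
    model = BackboneModel(
        np.array(["A"] * n + ["B"] * n, dtype="U4"),
        np.concatenate([np.arange(1, n + 1)] * 2),
        np.full(2 * n, "ALA", dtype="U3"),
        coords,
    )
    transform = Transform.rotation_about_axis([0.0, 0.0, 1.0], 120.0)
    from bundleforge.fusion import RingThresholds, build_ring

    check = build_ring(model, transform, 3, RingThresholds(max_close_err=1e-6))
    if not check.accepted:  # pragma: no cover - construction is exact
        raise FixtureError(f"wedge failed closure check: {check.rejection_reasons}")
    return Fixture(
        "c3-wedge",
        model,
        {
            "radius": radius,
            "helix_len": helix_len,
            "rotation_deg": 120.0,
            "close_err": check.close_err,
            "clash_count": check.clash_count,
        },
    )


def toy_dhr(
    seed: int = 0,
    n_repeats: int = 4,
    helix_len: int = 18,
    spacing: float = 10.0,
    repeat_shift: float = 21.0,
) -> Fixture:
    """Synthetic straight two-helix repeat protein (toy DHR stand-in).

    ``n_repeats`` up/down helix pairs along x, joined by short interpolated
    connectors into one chain; the terminal helices serve as N- and
    C-terminal splice windows of at least 14 residues.
    """
    base = CrickParams(supercoil_radius=0.0, supercoil_twist=0.0, length=helix_len)
    up = crick_ca_trace(base)
    down = up[::-1] + np.array([spacing, 0.0, 0.0])
    segments = []
    for r in range(n_repeats):
        shift = np.array([repeat_shift * r, 0.0, 0.0])
        segments.append(up + shift)
        segments.append(down + shift)
    ca_parts = [segments[0]]
    for seg in segments[1:]:
        prev_end = ca_parts[-1][-1]
        gap = np.linalg.norm(seg[0] - prev_end)
        n_conn = max(int(np.ceil(gap / 3.6)) - 1, 0)
        for k in range(1, n_conn + 1):
            ca_parts.append((prev_end + (seg[0] - prev_end) * k / (n_conn + 1))[None, :])
        ca_parts.append(seg)
    ca = np.concatenate(ca_parts)
    coords = backbone_from_ca(ca)
    n = len(ca)
    model = BackboneModel(
        np.full(n, "A", dtype="U4"),
        np.arange(1, n + 1),
        np.full(n, "ALA", dtype="U3"),
        coords,
    )
    manifest = {
        "n_repeats": n_repeats,
        "helix_len": helix_len,
        "n_residues": n,
        "n_window": helix_len,
        "c_window": helix_len,
    }
    if helix_len < 14:
        raise FixtureError("terminal splice windows must span >= 14 residues")
    return Fixture("toy-dhr", model, manifest)
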