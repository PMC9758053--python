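"""Parameter-grid enumeration and the staged six-helix bundle search.

Coiled-coil backbones are enumerated over a per-helix grid of helical phase,
supercoil radius and z offset, with supercoil phases fixed on the 60-degree
design lattice.  The six-helix search is staged: the three inner helices and
one outer helix are sampled first, surviving backbones (those hosting a
hydrogen-bond network, as judged by a caller-supplied test) seed the fifth
helix round, and stage-three survivors seed the sixth helix round, so each
stage only samples the newly added helix against retained parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Iterator, Sequence

from bundleforge.geometry import (
    OMEGA0_IDEAL,
    OMEGA1_IDEAL,
    BundleSpec,
    CrickParams,
)


class GridError(ValueError):
    """Empty or malformed parameter grid."""


def grid_values(lo: float, hi: float, step: float) -> tuple[float, ...]:
    """Inclusive arithmetic grid ``lo, lo+step, ..., hi``.

    Values are generated as ``lo + i*step`` from integer indices so repeated
    enumeration is drift-free.
    """
    if step <= 0:
        raise GridError("grid step must be positive")
    if hi < lo:
        raise GridError("grid upper bound below lower bound")
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + i * step, 9) for i in range(n))


@dataclass(frozen=True)
class HelixGrid:
    """Per-helix sampling axes; fixed supercoil phase, gridded dphi1/R/z."""

    supercoil_phase: float
    dphi1_values: tuple[float, ...]
    radius_values: tuple[float, ...]
    z_offsets: tuple[float, ...] = (0.0,)
    inverted: bool = False

    def __post_init__(self) -> None:
        if not (self.dphi1_values and self.radius_values and self.z_offsets):
            raise GridError("helix grid has an empty axis")

    @property
    def size(self) -> int:
        return len(self.dphi1_values) * len(self.radius_values) * len(self.z_offsets)

    def params(self, length: int) -> Iterator[CrickParams]:
        """Yield CrickParams in lexicographic (dphi1, R, z_off) order."""
        for dphi1, radius, z_off in product(
            self.dphi1_values, self.radius_values, self.z_offsets
        ):
            yield CrickParams(
                supercoil_radius=radius,
                supercoil_phase=self.supercoil_phase,
                helical_phase=dphi1,
                z_offset=z_off,
                supercoil_twist=OMEGA0_IDEAL,
                helical_twist=OMEGA1_IDEAL,
                length=length,
                inverted=self.inverted,
            )


@dataclass(frozen=True)
class GridSpec:
    """A bundle-level grid: one HelixGrid per helix plus the helix length."""

    helices: tuple[HelixGrid, ...]
    length: int = 77
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.helices:
            raise GridError("grid needs at least one helix")

    @property
    def size(self) -> int:
        n = 1
        for h in self.helices:
            n *= h.size
        return n


def coiled_coil_grid(spec: GridSpec) -> Iterator[BundleSpec]:
    """Enumerate every per-helix parameter combination of ``spec``.

    Deterministic lexicographic order: helix axes vary slowest-first, and
    within a helix the order is (dphi1, R, z_off).
    """
    if spec.size == 0:
        raise GridError("empty grid")
    per_helix = [tuple(h.params(spec.length)) for h in spec.helices]
    chain_ids = spec.chain_ids or tuple(
        "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[i] for i in range(len(spec.helices))
    )
    for combo in product(*per_helix):
        yield BundleSpec(combo, chain_ids)


def coiled_coil_gridspec(
    dphi1: tuple[float, float, float] = (-100.0, 100.0, 20.0),
    radius: tuple[float, float, float] = (6.5, 7.5, 0.25),
    z_offsets: Sequence[float] = (-1.5, 0.0, 1.5),
    length: int = 77,
    antiparallel: bool = False,
) -> GridSpec:
    """The three-helix coiled-coil design grid.

    Defaults follow the published protocol: helical phase -100..100 deg in
    20-deg steps, radius 6.5..7.5 A in 0.25-A steps, z offsets {-1.5, 0,
    1.5} A for helices 2 and 3 (zero for helix 1), 77-residue helices at
    supercoil phases 0/120/240.  ``antiparallel`` inverts the third helix.
    """
    dvals = grid_values(*dphi1)
    rvals = grid_values(*radius)
    zvals = tuple(z_offsets)
    helices = (
        HelixGrid(0.0, dvals, rvals, (0.0,)),
        HelixGrid(120.0, dvals, rvals, zvals),
        HelixGrid(240.0, dvals, rvals, zvals, inverted=antiparallel),
    )
    return GridSpec(helices, length=length, chain_ids=("A", "B", "C"))


_INNER_PHASES = (0.0, 120.0, 240.0)
_OUTER_PHASES = (60.0, 180.0, 300.0)


def bundle_stage_grids(
    inner_radius: tuple[float, float, float] = (6.5, 7.25, 0.375),
    outer_radius: tuple[float, float, float] = (12.25, 13.25, 0.5),
    dphi1: tuple[float, float, float] = (-100.0, 100.0, 20.0),
    z_offsets: Sequence[float] = (-1.5, 0.0, 1.5),
    length: int = 35,
    antiparallel: bool = False,
) -> tuple[GridSpec, HelixGrid, HelixGrid]:
    """Grids for the staged six-helix search.

    Returns the stage-1 grid (three inner helices at phases 0/120/240 plus
    one outer helix at 60) and the HelixGrids for the fifth (180) and sixth
    (300) helices, which mirror the fourth helix's axes.  ``antiparallel``
    inverts helices 3 and 6.
    """
    dvals = grid_values(*dphi1)
    ri = grid_values(*inner_radius)
    ro = grid_values(*outer_radius)
    zvals = tuple(z_offsets)
    stage1 = GridSpec(
        (
            HelixGrid(_INNER_PHASES[0], dvals, ri, (0.0,)),
            HelixGrid(_INNER_PHASES[1], dvals, ri, zvals),
            HelixGrid(_INNER_PHASES[2], dvals, ri, zvals, inverted=antiparallel),
            HelixGrid(_OUTER_PHASES[0], dvals, ro, zvals),
        ),
        length=length,
        chain_ids=("A", "B", "C", "D"),
    )
    helix5 = HelixGrid(_OUTER_PHASES[1], dvals, ro, zvals)
    helix6 = HelixGrid(_OUTER_PHASES[2], dvals, ro, zvals, inverted=antiparallel)
    return stage1, helix5, helix6


@dataclass
class StageResult:
    """Survivors of one search stage with their network evidence."""

    stage: int
    survivors: list[BundleSpec] = field(default_factory=list)
    evidence: list[object] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.survivors)


class StageSearchError(RuntimeError):
    """A network-test callback failed; carries the offending spec."""

    def __init__(self, spec: BundleSpec, cause: Exception):
        super().__init__(f"network test failed on {spec}: {cause}")
        self.spec = spec
        self.cause = cause


def _spec_key(spec: BundleSpec) -> tuple:
    return tuple(
        (
            round(h.supercoil_phase, 3),
            round(h.helical_phase, 3),
            round(h.supercoil_radius, 3),
            round(h.z_offset, 3),
            h.inverted,
        )
        for h in spec.helices
    )


def _extend_spec(parent: BundleSpec, new_helix: CrickParams, chain_id: str) -> BundleSpec:
    return BundleSpec(parent.helices + (new_helix,), parent.chain_ids + (chain_id,))


def stepwise_bundle_search(
    stage1: GridSpec,
    extra_stages: Sequence[HelixGrid],
    network_test: Callable[[BundleSpec], object],
    max_stage1: int | None = None,
) -> list[StageResult]:
    """Run the staged search: filter stage 1, then grow one helix per stage.

    ``network_test`` is called on every candidate BundleSpec and must return
    a truthy value (the network evidence) for the spec to survive.  Stages
    after the first enumerate only the new helix's grid against each
    retained parent.  Survivors are deduplicated on parameters rounded to 3
    decimals.  ``max_stage1`` optionally caps the number of stage-1
    candidates evaluated (for smoke runs on huge grids).
    """
    results: list[StageResult] = []
    stage_num = 1
    result = StageResult(stage_num)
    seen: set[tuple] = set()
    for i, spec in enumerate(coiled_coil_grid(stage1)):
        if max_stage1 is not None and i >= max_stage1:
            break
        evidence = _run_test(network_test, spec)
        if evidence:
            key = _spec_key(spec)
            if key not in seen:
                seen.add(key)
                result.survivors.append(spec)
                result.evidence.append(evidence)
    results.append(result)

    for grid in extra_stages:
        stage_num += 1
        nxt = StageResult(stage_num)
        seen = set()
        chain_id = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[
            len(results[-1].survivors[0].helices) if results[-1].survivors else 0
        ]
        for parent in results[-1].survivors:
            for new_helix in grid.params(stage1.length):
                spec = _extend_spec(parent, new_helix, chain_id)
                evidence = _run_test(network_test, spec)
                if evidence:
                    key = _spec_key(spec)
                    if key not in seen:
                        seen.add(key)
                        nxt.survivors.append(spec)
                        nxt.evidence.append(evidence)
        results.append(nxt)
    return results


def _run_test(network_test: Callable[[BundleSpec], object], spec: BundleSpec):
    try:
        return network_test(spec)
    except Exception as exc:  # propagate with the offending spec attached
        raise StageSearchError(spec, exc) from exc


def checkpoint_indices(specs: Iterable[BundleSpec], grid: GridSpec) -> list[int]:
    """Indices of ``specs`` within the deterministic enumeration of ``grid``."""
    keys = {_spec_key(s): None for s in specs}
    out = []
    for i, spec in enumerate(coiled_coil_grid(grid)):
        if _spec_key(spec) in keys:
            out.append(i)
    return out
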