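# Methods

## Backbone model

Helices are generated from the generalized Crick parameterization (see the
README for the closed form). Constants are the conventional ideal-helix
values: minor radius R₁ = 2.26 Å, rise per residue d = 1.51 Å, and the
pitch angle α defined by sin α = R·ω₀/d. With ω₀ = −2.85°/res and
ω₁ = 102.85°/res the supercoil is left-handed (the helix-axis track winds
clockwise viewed down +z) and the phase of a residue about its own helix
axis, measured in the supercoil frame, repeats every 7 residues to within
0.05° — the heptad periodicity that the register logic relies on.

Full backbones are produced by decorating the CA trace with a rigid
residue template: a poly-Ala helix is built once by internal coordinates
at the canonical α torsions (φ = −57.8°, ψ = −47.0°, ω = 180°, standard
bond lengths/angles), and the central residue's N, C, O and CB are stored
in a local frame spanned by the smoothed chain tangent and the inward
curvature bisector at each CA. The exact (102.85°/res, 1.51 Å) twist/rise
pair is not reachable with ideal peptide bond geometry (at that twist the
rise comes out near 1.65 Å), so the canonical frame is used instead; the
resulting torsions of decorated backbones stay within ±5° of the canonical
values and comfortably inside the α basin (φ = −60 ± 20°, ψ = −45 ± 20°),
and consecutive CA distances stay within 3.8 ± 0.15 Å. Chain ends are
completed either exactly (generated helices evaluate the Crick curve one
residue past each end) or, for read-in CA traces, by extrapolating with
the chain's own per-residue screw transform fitted over the terminal
eight residues (worst-case end-atom deviation ≈ 0.1 Å on supercoiled
helices).

Antiparallel helices are built by a 180° rotation about the radial axis
through the helix centroid, which preserves the supercoil radius and the
phase lattice. Bundle specs restrict supercoil phases to the 60° design
lattice {0, 60, ..., 300}, force Z_off = 0 on the first helix, and flag
(rather than reject) helix pairs whose axis tracks come within 6 Å.

## Grid sampling and the staged search

Grids are enumerated as integer-index × step so repeated runs are
drift-free, with both endpoints included. The coiled-coil defaults are
the published protocol values (Δφ₁ −100..100° step 20°, R 6.5..7.5 Å step
0.25 Å, Z_off {−1.5, 0, 1.5} Å for helices 2 and 3, 77-residue helices);
the staged six-helix search uses R 6.5..7.25 step 0.375 Å inside,
12.25..13.25 step 0.5 Å outside, 35-residue helices, with the fifth and
sixth helices sampled over the same axes as the fourth. Stages after the
first enumerate only the new helix against each retained parent; survivors
are deduplicated on parameters rounded to three decimals. The search is
generic over its `network_test` callback, so a cheap geometric filter or
the full Monte Carlo network search can stand behind the same staging.

## Register, masks and layers

The heptad letter offset is chosen per chain so that 'a' falls on the
position class whose CA→CB vectors point most directly at the bundle axis
(mean inwardness over every seventh residue); letters then advance
cyclically. Core-facing positions are letters a and d plus g at trimer
interfaces (g participates in the shared three-chain interface), with an
additional 60° angular cut between CA→CB and the inward axis direction.
Heptad blocks for masking are positional (residues i//7), so a 77-residue
chain always has 11 heptads; N/P patterns shorter than the chain are
centered with ties broken toward the N terminus (the protocol names the
patterns but not their offset). Layer design is rule-based: core letters
get Leu with at least two Phe placed at the most central core sites,
surface letters b/c/f alternate Glu/Lys by residue parity, remaining
letters get Ala, and hydrogen-bond-network positions always win (with a
warning when they override a core rule). No packing energy is computed
anywhere — that is deliberate scope, not simplification of an existing
dependency.

## Rotamers and hydrogen bonds

Sidechains are built from each residue's backbone frame by vectorized
internal-coordinate placement. Chi grids: staggered {−60, 60, 180}° for
sp3 chis, {−90, 0, 90}° for terminal sp2 chis, a 30° grid for
ring chis (His/Tyr/Trp); extra-rotamer mode adds ±20° sub-rotamers around
every non-ring chi value (Ser: 3 → 9 rotamers). The allowed set defaults
to the polar types plus Asp/Glu — S, T, N, Q, H, Y, W, D, E — with
Lys/Arg available behind an explicit flag, since long flexible cations
rarely survive in buried designed networks.

A hydrogen bond is purely geometric on heavy atoms: donor–acceptor
distance in [2.6, 3.3] Å, angle at the donor (base–donor–acceptor, the
implicit-H proxy) ≥ 120°, angle at the acceptor ≥ 90°; all three are
configurable. Clashes use a hard-sphere 2.8 Å cutoff against backbone and
other placements. The detector is KD-tree pruned and is tested for exact
agreement against a plain all-pairs oracle.

The Monte Carlo search precomputes every placement at the masked
positions plus their pairwise bond/clash adjacency, then runs cheap graph
walks: each trial seeds a uniformly random placement and repeatedly picks
a random bond-forming, clash-free extension until stuck. Trials are
seeded as `default_rng([seed, trial])`, so a longer run reproduces and
strictly extends a shorter one, and results are invariant under rigid-body
motion of the input (all geometry is relative). Networks are kept when
they reach the size and chain-span constraints and deduplicated by their
position→type map; cross-network rules (three networks per trimer, at
least two Tyr/Trp in total) are evaluated over combinations of
position-disjoint networks. Satisfaction counts a polar heavy atom as
satisfied when it participates in any detected bond (side-chain or
backbone) or lies outside a burial radius — a distance-from-axis proxy for
solvent exposure (default: maximal CA axis distance + 3 Å), adequate for
parametric bundles where burial is monotone in radius; a network passes
only if every buried polar atom is satisfied.

## Species, trimming and loops

Off-target species are unordered multisets over the chain alphabet up to
the assembly size, minus the target. Two listing conventions exist
because the two published counts use different ones: `full` keeps
homotypic dimers (AB design → A, B, AA, BB = 4), `paper-trimer` drops them
(ABC design → 15). Both are first-class; no intent is guessed.

Trimming removes whole heptads from the C terminus by default (the
protocol trims to stagger termini but does not name the end; the choice is
configurable), renumbers from 1 and preserves register letters modulo the
shift. Hairpin pairings are pure combinatorics; loop feasibility uses a
span rule d_max(n) = 3.3 Å·(n+1) for an n-residue loop — an extended-chain
bound, standing in for fragment-based loop validation, which is out of
scope — with end adjustments from −3 (deletion) to +2 (extension)
residues, extensions projecting along the terminal CA direction.

## Fusions and rings

Splices superpose the donor's C-terminal CA window onto the acceptor's
N-terminal window over every admissible deletion pair (defaults: up to 7
residues on the bundle side, one full repeat on the repeat-protein side)
and overlap length (minimum 8 residues, more than one helical turn, chosen
because shorter overlaps under-determine the junction frame); the
lowest-RMSD overlap wins and the fused chain takes the acceptor's geometry
across the junction. `close_err` is defined as the RMSD between a probe
structure and the probe moved by the n-fold composed propagation
transform: dimensionally Å, zero exactly at closure, lever-arm aware, and
with the closed form n·δ for a pure axial offset δ. The `score0`
analogue is the count of inter-copy backbone heavy-atom pairs closer than
3.0 Å — it preserves the filter semantics of an energy screen without an
energy function. Ring solutions record all three filter values and the
reasons for rejection; the full ring model is emitted only on acceptance.

## Synthetic fixtures

All test inputs are generated programmatically and self-verified at build
time. The planted-triad fixture is an ideal C3 trimer (R = 7 Å, 35
residues) whose central polar heptads are exhaustively searched over
Ser/Thr/Asn extra-rotamers for the first connected, clash-free,
three-chain triad in deterministic order; its hydrogen bonds are
re-checked with the detector before the fixture is accepted, so the Monte
Carlo recovery test runs against a guaranteed-present network. The C3
wedge places two straight helices inside one 120° sector at radius 12 Å,
making the exact rotation its junction transform; the toy repeat protein
is four straight up/down helix pairs joined by short interpolated
connectors, with 18-residue terminal splice windows. These fixtures
emulate the geometry of designed bundles and repeat proteins but none of
their sequence energetics, solvation or backbone irregularity — passing
tests demonstrate correctness of the geometric pipeline, not designability
of real proteins.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 1,497,375-spec grid
enumeration (a few seconds), 1,000-trial Monte Carlo searches on the
35-residue fixture with the Ser/Thr/Asn alphabet, and 50-instance oracle
comparisons; the full nine-type extra-rotamer index on a 35-residue trimer
(≈14,000 placements) builds in well under a minute and a 100,000-trial
search over it completes in about a minute. Angles are degrees and
lengths Å in every interface; radians appear only inside formulas.
Superposition excludes reflections (determinant-corrected SVD) and rejects
collinear selections; grid floats are produced from integer indices;
Monte Carlo determinism comes from per-trial sub-seeds.

## Known limitations

No packing, solvation or electrostatic energies; no sequence optimization
beyond the layer rules; no loop coordinate building (feasibility only); no
structure-prediction-based filtering. The hydrogen-bond model is
geometric and orientation-coarse (implicit hydrogens), so it over-accepts
relative to an energy-based definition; conversely the hard-sphere clash
model over-rejects tightly packed rotamers. Burial is a radial proxy and
is only meaningful for roughly cylindrical assemblies.
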