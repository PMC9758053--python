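# bundleforge

Computational design tools for **obligate ABC-type heterotrimeric helical
bundles**: three distinct protein chains that assemble in 1:1:1
stoichiometry while every alternative species (monomers, homodimers,
heterodimers, non-ABC trimers) is disfavored. The package is written for
protein designers and structural bioinformaticians who want the backbone
generation, hydrogen-bond-network search and assembly bookkeeping of this
design strategy as an importable, testable Python library.

## What it does

**Parametric backbones.** Helices follow the generalized Crick coiled-coil
parameterization. Each helix is placed by a supercoil radius *R*,
supercoil phase Δφ₀, helical phase Δφ₁, z offset *Z*_off and the twists
ω₀ (supercoil) and ω₁ (helical), with the CA curve

```
x(t) = R·cos(ω₀t+φ₀) + R₁·cos(ω₀t+φ₀)cos(ω₁t+φ₁) − R₁·cosα·sin(ω₀t+φ₀)sin(ω₁t+φ₁)
y(t) = R·sin(ω₀t+φ₀) + R₁·sin(ω₀t+φ₀)cos(ω₁t+φ₁) + R₁·cosα·cos(ω₀t+φ₀)sin(ω₁t+φ₁)
z(t) = d·t·cosα − R₁·sinα·sin(ω₁t+φ₁) + Z_off ,   sinα = R·ω₀/d
```

with minor radius R₁ = 2.26 Å and rise d = 1.51 Å. The ideal twists
ω₀ = −2.85°/res and ω₁ = 102.85°/res give a left-handed supercoil with 3.5
residues per turn and the classic seven-residue (heptad, a–g) repeat.
Full N/C/O/CB backbones are built by decorating the CA trace with an ideal
α-helical residue frame.

**Grid sampling.** The three-helix design grid (Δφ₁ from −100° to 100° by
20°, *R* from 6.5 to 7.5 Å by 0.25 Å, Z_off ∈ {−1.5, 0, 1.5} Å for helices
2 and 3) enumerates (11·5)³·3² = 1,497,375 backbones deterministically.
Six-helix bundles are searched in three stages: inner helices plus one
outer helix first, then the fifth and sixth helices are sampled only
against surviving backbones.

**Hydrogen-bond networks.** Polar rotamers (Ser/Thr/Asn/Gln/His/Tyr/Trp
plus Asp/Glu) are placed on discrete chi grids at core positions of polar
(P) heptads, and a seeded Monte Carlo search grows connected,
clash-free hydrogen-bond networks that must span all three chains.
Network satisfaction demands that every buried donor/acceptor heavy atom
finds a partner — the buried polar core that gives the heterotrimer its
specificity, helped by Tyr/Trp aromatics as implicit negative design.

**Topology and negative design.** `enumerate_species` lists the
alternative assemblies a design must out-compete (4 for a two-chain AB
design; 15 for ABC under the standard listing convention). Chains are
trimmed in whole heptads (49/63/77 staggering), and six-helix bundles are
closed into three hairpin chains clockwise (A–D; B–E; C–F) or
counterclockwise (A–F; B–E; C–D) with 2–5-residue loop feasibility checks.

**Fusions and rings.** Building blocks fuse rigidly by superposing
overlapping helical windows at their termini (lowest overlap RMSD wins),
and fusions propagate into C2–C5 cyclic rings filtered on chain length,
inter-copy clashes (`score0`) and ring closure error (`close_err` — the
RMSD between a probe and its n-fold transformed copy).

## Worked example

`python examples/03_search_networks.py` builds a C3 trimer backbone whose
core verifiably hosts a Ser/Thr/Asn triad, masks the central polar heptads
(pattern N–P–P–P–N) and runs 1,000 Monte Carlo trials:

```
planted triad: ['A13:ASN', 'B13:SER', 'C13:ASN']
searchable positions: 18
26 unique networks spanning all three chains:
  [B20:ASN, C20:ASN, A20:SER]  bonds=2  satisfaction=0.80  buried_ok=False
  [A27:ASN, B27:ASN, C27:ASN, A23:ASN]  bonds=3  satisfaction=0.62  buried_ok=False
  ...
```

Each line is one deduplicated network: its member residues, the number of
detected hydrogen bonds, and the fraction of polar heavy atoms that are
either bonded or solvent-exposed (1.0 would mean a fully satisfied,
designable network). The other examples cover backbone building, grid
sampling, species/trimming bookkeeping and fusion/ring closure — each
prints the quantities it computes and what they mean.

A thin CLI mirrors the library (`bundleforge sample-cc`, `hbnet-search`,
`enumerate-species`, `close-loops`, `fuse`, `ring-close`, `superpose`,
`make-fixture`).

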