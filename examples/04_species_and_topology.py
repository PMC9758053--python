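"""Off-target species bookkeeping, chain trimming and hairpin pairing.

An obligate ABC heterotrimer must out-compete every alternative assembly:
4 species for a two-chain design, 15 for three chains under the standard
listing convention.  The staggered 49/63/77 chain lengths come from
trimming the 77-residue trimer by four and two heptads; hairpin pairing
and loop feasibility close a six-helix bundle into three chains.
"""

from bundleforge import (
    BundleSpec,
    CrickParams,
    assemble_bundle,
    enumerate_species,
    hairpin_pairings,
    loop_feasibility,
    trim_chains,
)

dimer = enumerate_species("AB", 2, target="AB", convention="full")
print(f"two-chain design: {dimer.count} alternative species: {dimer.members}")
trimer = enumerate_species("ABC", 3, target="ABC", convention="paper-trimer")
print(f"three-chain design: {trimer.count} alternative species")

model = assemble_bundle(
    BundleSpec(
        tuple(CrickParams(supercoil_phase=p, length=77) for p in (0, 120, 240)),
        ("A", "B", "C"),
    )
)
trimmed = trim_chains(model, {"A": 4, "B": 2})
lengths = {c: int(trimmed.chain_mask(c).sum()) for c in "ABC"}
print(f"staggered chain lengths after trimming: {lengths}")

six = assemble_bundle(
    BundleSpec(
        tuple(
            [CrickParams(supercoil_phase=p, supercoil_radius=7.0, length=35)
             for p in (0, 120, 240)]
            + [CrickParams(supercoil_phase=p, supercoil_radius=13.0, length=35,
                           inverted=True)
               for p in (60, 180, 300)]
        ),
        tuple("ABCDEF"),
    )
)
scheme = hairpin_pairings("clockwise")
print(f"clockwise hairpin pairing: {scheme.pairs}")
for pair, opt in loop_feasibility(six, scheme).items():
    print(f"  {pair[0]}-{pair[1]}: gap {opt.gap:.1f} A -> "
          f"{'feasible' if opt.feasible else 'infeasible'} "
          f"with a {opt.loop_len}-residue loop")
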