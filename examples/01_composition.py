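"""Design a 40 nm model sea-spray particle and inspect its composition.

The builder pins the water mass fraction at 0.51, sets ion counts from the
target molarities (0.4 M NaCl, plus seawater minor ions in systems B/C), and
gives the remaining mass to the organic mixture, whose internal split is what
distinguishes systems A, B and C.
"""

from aeromorph.composition import build_composition, fatty_acid_organic_share, molarity

for system_id in ("A", "B", "C"):
    spec, counts = build_composition(system_id, diameter=400.0)
    fractions = counts.achieved_mass_fractions
    n_water = counts.counts["water"]
    nacl = min(counts.counts["Na+"], counts.counts["Cl-"])
    print(f"system {system_id}: {sum(counts.counts.values()):,} molecules")
    print(
        f"  mass fractions  water {fractions['water']:.3f}  "
        f"organic {fractions['organic']:.3f}  inorganic {fractions['inorganic']:.3f}"
    )
    print(
        f"  organic split   FA {100 * fatty_acid_organic_share(counts):.1f}%  "
        f"BCL {100 * counts.organic_shares['BCL']:.1f}%"
    )
    print(f"  salinity        NaCl {molarity(nacl, n_water):.3f} M")
    if "Mg2+" in counts.counts:
        print(f"  minor ions      Mg2+ {1000 * molarity(counts.counts['Mg2+'], n_water):.0f} mM")
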