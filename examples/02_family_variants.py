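"""Observe within-family sequence variants.

Builds a small family of near-identical members, aligns it center-star
around the representative, and reports the columns where members disagree
with the consensus — the family's candidate mutations."""

from smorfscape import (
    ProteinRecord,
    SmallProteinFamily,
    align_center_star,
    call_variants,
    consensus_sequence,
)

base = "MKTLILGASLLVAGSAFAQTNPFAEQIKSGDLVVTGKVESNPLAEQYKAM"
mutant = base[:10] + "R" + base[11:30] + "E" + base[31:44] + "W" + base[45:]
members = [
    ProteinRecord(id="m0", sequence=base),
    ProteinRecord(id="m1", sequence=base),
    ProteinRecord(id="m2", sequence=base),
    ProteinRecord(id="m3", sequence=mutant),  # three substitutions
]
family = SmallProteinFamily(family_id="m0", representative=members[0],
                            members=members)

alignment = align_center_star(family)
print(f"alignment: {len(alignment.rows)} rows x {alignment.n_columns} columns")

sites = call_variants(alignment)
print(f"variant sites: {len(sites)}")
for site in sites:
    alts = ", ".join(f"{res}x{count}" for res, count in site.alternates)
    print(f"  column {site.column}: consensus {site.consensus_residue}, "
          f"alternates {alts}, conservation {site.conservation:.2f}")

consensus = consensus_sequence(alignment)
print(f"consensus ({consensus.length} aa): {consensus.sequence}")
print("Conservation is the modal-residue fraction per column; a site is any "
      "column where at least one member departs from the mode.")
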