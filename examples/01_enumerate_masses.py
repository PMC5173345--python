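"""Enumerate ganglioside molecular species and their ion m/z values.

Builds the (class x ceramide x charge) candidate space for the 14-class SRM
panel and the 19-species ceramide panel, and prints a few rows: the neutral
monoisotopic mass of each species and the m/z of its deprotonated ions, plus
the diagnostic sialic-acid fragment used for precursor-ion scanning.
"""

from gangliomics import core, pipeline

table = pipeline.enumerate_species_table()
print(f"{len(table)} candidate ions across {table['class'].nunique()} classes")
print(table.head(8).to_string(index=False))

# The fragment anion at nominal m/z 290 is the reporter every ganglioside
# yields in negative-mode CID: dehydrated, deprotonated N-acetylneuraminate.
print(f"\nsialic fragment m/z: {core.sialic_fragment_mz():.3f} (nominal 290)")

# GM3 carries one sialic acid, so it can only form [M-H]-; GQ1b carries four
# and forms up to [M-4H]4-.
gm3 = table[table["class"] == "GM3"]
gq1b = table[table["class"] == "GQ1b"]
print(f"GM3 charge states: {sorted(int(x) for x in gm3['charge'].unique())}")
print(f"GQ1b charge states: {sorted(int(x) for x in gq1b['charge'].unique())}")
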