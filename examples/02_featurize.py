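"""Build the 157-dimensional feature vector for a peptide.

Each residue position (0 = initiator Met, 1-4 the variable tetrapeptide) is
described by 26 published descriptor components (Z-scale 5, T-scale 5,
ST-scale 8, VHSE-scale 8); together with the 26 sequence averages and the
mRNA ensemble energy of the ORF prefix this gives 157 named features.
"""

from teploop import CodonUsageTable, encode_peptide, ensemble_energy, load_scales

scales = load_scales()
table = CodonUsageTable.load()

energy = ensemble_energy("SKIK", table)
fv = encode_peptide("SKIK", scales, energy.energy)

print(f"feature count: {len(fv)}")
print(f"ensemble energy of the SKIK ORF prefix: {energy.energy:.2f} kcal/mol")
print(f"z1_3 (Z-scale lipophilicity, position 3): {fv['z1_3']:+.2f}")
print(f"z1 (sequence average over positions 0-4): {fv['z1']:+.3f}")
print(f"T3_4 (T-scale component 3, position 4):  {fv['T3_4']:+.2f}")
# Positional features carry a "_p" suffix; unsuffixed names are sequence
# averages; "energy" is the single mRNA-level feature.  More negative energy
# means a more stably folded 33-nt prefix around the start codon.
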