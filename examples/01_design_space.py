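"""Enumerate the tetrapeptide design space and map peptides to DNA.

The design unit is a four-residue peptide inserted between the initiator
methionine and the SecM arrest peptide of the reporter.  This script counts
the space, inspects the NNK degenerate-codon library used to build it in the
lab, and reverse-translates a peptide with CAI-optimal E. coli codons.
"""

from teploop import (
    CodonUsageTable,
    build_orf_prefix,
    enumerate_tetrapeptides,
    nnk_codon_set,
    reverse_translate_cai,
)

space = enumerate_tetrapeptides()
print(f"design space: {len(space):,} tetrapeptides "
      f"({space[0]} ... {space[-1]}, lexicographic)")

nnk = nnk_codon_set()
print(f"NNK library: {len(nnk.codons)} codons covering "
      f"{len(nnk.amino_acids)} amino acids; stop codons: {nnk.stop_codons}")
# 32 codons encode all 20 residues; the only stop that survives K = G/T in
# the wobble position is the amber codon TAG.

table = CodonUsageTable.load()
dna = reverse_translate_cai("SKIK", table)
prefix = build_orf_prefix("SKIK", table)
print(f"SKIK reverse-translated with major codons: {dna}")
print(f"11-codon ORF prefix (ATG + SKIK + SecM context): {prefix.dna}")
# The 33-nt prefix is the sequence whose mRNA folding stability becomes the
# model's "energy" feature.
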