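"""Normalize, deduplicate and label a peptide-activity table.

All fluorescence values are expressed relative to the SKIK reference
peptide (SKIK = 1); a record is "positive" when it strictly surpasses the
reference.
"""

from teploop import (
    ActivityTable,
    classify_positive,
    deduplicate_average,
    normalize_to_reference,
)

table = ActivityTable.from_records(
    [
        {"peptide": "no_peptide", "raw_intensity": 16.0},
        {"peptide": "SKIK", "raw_intensity": 86.0},
        {"peptide": "VSVD", "raw_intensity": 111.8},
        {"peptide": "VSVD", "raw_intensity": 110.0},  # resequenced duplicate
        {"peptide": "ISMD", "raw_intensity": 86.0},
    ]
)

normalized = normalize_to_reference(table)
print(normalized.df[["peptide", "relative_intensity"]].to_string(index=False))
# The no-peptide control lands at 16/86 = 0.186; SKIK is exactly 1.

unique = deduplicate_average(normalized)
vsvd = unique.df.loc[unique.df.peptide == "VSVD", "relative_intensity"].iloc[0]
print(f"VSVD after duplicate averaging: {vsvd:.3f} (mean of 2 records)")

labels = classify_positive(unique)
positives = unique.df.loc[labels.to_numpy(), "peptide"].tolist()
print(f"positives (strictly above SKIK): {positives}")
# ISMD ties the reference at 1.0 and is therefore NOT positive.
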