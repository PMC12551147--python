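"""Sequence logos, dipeptide adjacency, and residue-property regression."""

from teploop import (
    dipeptide_adjacency,
    information_content,
    position_frequency_matrix,
    residue_property_regression,
)
from teploop.analysis import KD_HYDROPATHY, top_dipeptides

top_set = ["NNDD", "NSDD", "SNDD", "NTDD", "NDDD", "NNSD", "SKIK", "NNND"]

pfm = position_frequency_matrix(top_set)
ic = information_content(pfm)
print("per-position information content (bits):",
      " ".join(f"{b:.2f}" for b in ic))
print(f"freq(D, position 4) = {pfm.freqs.loc['D', 4]:.2f}")
# High bits mean a position is strongly constrained; 4.32 bits would be a
# single invariant residue, 0 a uniform column.

adj = dipeptide_adjacency(top_set)
print("top-5 adjacent residue pairs:", top_dipeptides(adj, 5))
# These ordered pair counts are the data behind a Sankey-style flow diagram.

# Regress per-variant activity on a per-residue property (demo table only:
# Kyte-Doolittle hydropathy, not the original side-chain parameter set).
activity = {aa: 1.5 - 0.1 * KD_HYDROPATHY[aa] for aa in "DENQKAVLIF"}
fit = residue_property_regression(activity, KD_HYDROPATHY)
print(f"activity ~ hydropathy: slope {fit.slope:+.2f}, R^2 = {fit.r_squared:.2f}")
# A negative slope with high R^2 indicates hydrophilic fourth residues track
# with stronger translation enhancement in this constructed illustration.
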