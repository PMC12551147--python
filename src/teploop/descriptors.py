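"""Amino-acid descriptor scales and the 157-dimensional peptide feature vector.

Four published descriptor sets encode each residue numerically: the Z-scale
(5 components, physicochemical), T-scale (5, topological), ST-scale (8,
structural/topological) and VHSE-scale (8, hydrophobic/steric/electronic) —
26 components per residue in total.  Each component is evaluated at the five
residue positions of the expressed peptide (position 0 is the initiator Met,
positions 1-4 the variable tetrapeptide) and as the sequence average, giving
26 x 6 = 156 amino-acid-based features.  The mRNA ensemble free energy of the
11-codon ORF prefix adds one more ("energy") for a total of 157.

Naming convention: positional features carry a suffix ("z1_3" = Z-scale
component 1 at position 3); the sequence average has no suffix ("z1"); the
energy feature is simply "energy".  Position-0 features are constant across
peptides (always Met) but are retained, matching the 157-feature count.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_space import AMINO_ACIDS, validate_peptide

#: scale name -> (feature-name prefix, expected component count, data file)
SCALE_SPECS = {
    "zscale": ("z", 5, "zscale.tsv"),
    "tscale": ("T", 5, "tscale.tsv"),
    "stscale": ("ST", 8, "stscale.tsv"),
    "vhsescale": ("VHSE", 8, "vhsescale.tsv"),
}

N_POSITIONS = 5  # initiator Met + 4 variable residues
N_COMPONENTS = 26  # 5 + 5 + 8 + 8
N_FEATURES = N_COMPONENTS * (N_POSITIONS + 1) + 1  # 157


class ScaleIntegrityError(ValueError):
    """A descriptor table violates its contract (coverage/width)."""


class EncodingError(ValueError):
    """Peptides and auxiliary inputs cannot be aligned into a feature matrix."""


@dataclass(frozen=True)
class DescriptorScale:
    """One descriptor set: a fixed-length numeric vector per amino acid."""

    name: str
    prefix: str
    values: Mapping[str, np.ndarray]
    n_components: int

    @property
    def component_names(self) -> list[str]:
        return [f"{self.prefix}{i + 1}" for i in range(self.n_components)]

    def matrix(self) -> np.ndarray:
        """(20, n_components) array in :data:`AMINO_ACIDS` order."""
        return np.vstack([self.values[aa] for aa in AMINO_ACIDS])


def _parse_scale(name: str, text: str) -> DescriptorScale:
    prefix, n_comp, _ = SCALE_SPECS[name]
    values: dict[str, np.ndarray] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        parts = line.split("\t")
        aa, comps = parts[0], parts[1:]
        if len(comps) != n_comp:
            raise ScaleIntegrityError(
                f"{name}: residue {aa!r} has {len(comps)} components, "
                f"expected {n_comp}"
            )
        values[aa] = np.asarray([float(c) for c in comps])
    missing = set(AMINO_ACIDS) - set(values)
    if missing:
        raise ScaleIntegrityError(f"{name}: missing residues {sorted(missing)}")
    extra = set(values) - set(AMINO_ACIDS)
    if extra:
        raise ScaleIntegrityError(f"{name}: unknown residues {sorted(extra)}")
    return DescriptorScale(name=name, prefix=prefix, values=values, n_components=n_comp)


def load_scales(data_dir=None) -> dict[str, DescriptorScale]:
    """Load and validate the four bundled descriptor scales.

    ``data_dir`` overrides the bundled tables with a directory holding files
    of the same names (zscale.tsv, tscale.tsv, stscale.tsv, vhsescale.tsv).
    """
    scales: dict[str, DescriptorScale] = {}
    for name, (_, _, fname) in SCALE_SPECS.items():
        if data_dir is None:
            text = (resources.files("teploop.data") / fname).read_text()
        else:
            with open(f"{data_dir}/{fname}") as fh:
                text = fh.read()
        scales[name] = _parse_scale(name, text)
    return scales


def component_names(scales: Mapping[str, DescriptorScale]) -> list[str]:
    """The 26 component names in canonical scale order."""
    names: list[str] = []
    for name in SCALE_SPECS:
        names.extend(scales[name].component_names)
    return names


def descriptor_matrix(scales: Mapping[str, DescriptorScale]) -> np.ndarray:
    """(20, 26) matrix of all components, rows in :data:`AMINO_ACIDS` order."""
    return np.hstack([scales[name].matrix() for name in SCALE_SPECS])


def feature_names(scales: Mapping[str, DescriptorScale]) -> list[str]:
    """Canonical order of the 157 features.

    For each component c (scales in z/T/ST/VHSE order): c_0, c_1, c_2, c_3,
    c_4 then the unsuffixed sequence average c; the single "energy" feature
    comes last.
    """
    names: list[str] = []
    for comp in component_names(scales):
        names.extend(f"{comp}_{p}" for p in range(N_POSITIONS))
        names.append(comp)
    names.append("energy")
    return names


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MET_INDEX = _AA_INDEX["M"]


def _residue_indices(peptides: Sequence[str]) -> np.ndarray:
    """(n, 5) integer residue indices including the leading Met."""
    n = len(peptides)
    idx = np.empty((n, N_POSITIONS), dtype=np.intp)
    idx[:, 0] = _MET_INDEX
    for r, p in enumerate(peptides):
        validate_peptide(p)
        for j, aa in enumerate(p):
            idx[r, j + 1] = _AA_INDEX[aa]
    return idx


def encode_table(
    peptides: Sequence[str],
    scales: Mapping[str, DescriptorScale],
    energies: Iterable[float],
    dtype=np.float64,
) -> pd.DataFrame:
    """Encode peptides into the (n, 157) feature matrix.

    Rows align with the peptide order; columns follow :func:`feature_names`.
    One finite energy value (kcal/mol) is required per peptide.
    """
    energies = np.asarray(list(energies), dtype=float)
    if energies.shape != (len(peptides),):
        raise EncodingError(
            f"{len(peptides)} peptides but {energies.size} energies"
        )
    names = feature_names(scales)
    n = len(peptides)
    out = np.empty((n, N_FEATURES), dtype=dtype)
    if n:
        if not np.all(np.isfinite(energies)):
            raise EncodingError("energies must be finite")
        idx = _residue_indices(peptides)
        D = descriptor_matrix(scales)  # (20, 26)
        gathered = D[idx]  # (n, 5, 26)
        for c in range(N_COMPONENTS):
            base = c * (N_POSITIONS + 1)
            out[:, base : base + N_POSITIONS] = gathered[:, :, c]
            out[:, base + N_POSITIONS] = gathered[:, :, c].mean(axis=1)
        out[:, -1] = energies
    return pd.DataFrame(out, columns=names)


def encode_peptide(
    peptide: str,
    scales: Mapping[str, DescriptorScale],
    energy: float,
) -> pd.Series:
    """The 157 named explanatory variables for one peptide."""
    df = encode_table([peptide], scales, [energy])
    return df.iloc[0]
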