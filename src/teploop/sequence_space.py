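"""Tetrapeptide design space, NNK degenerate-codon library, and codon-level mapping.

The design unit is a tetrapeptide: four residues over the 20 standard amino
acids, inserted directly after the initiator methionine and upstream of the
SecM arrest peptide in the reporter ORF.  This module enumerates the full
20**4 = 160,000-sequence space, describes the (NNK)4 library used to build it
experimentally, and maps peptides back to DNA with CAI-optimal codons so that
the mRNA-level "energy" feature can be computed on a fixed 11-codon ORF prefix
(ATG + 4 randomized codons + the first 6 SecM arrest-peptide codons).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from Bio.Seq import Seq

#: The 20 standard amino acids in alphabetical one-letter-code order.  This
#: ordering fixes the enumeration order of the design space and every
#: downstream lexicographic tie-break.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PEPTIDE_LENGTH = 4
START_CODON = "ATG"

#: Fixed downstream context of the randomized region: the first six codons of
#: the SecM arrest peptide (F-S-T-P-V-W) exactly as they appear in the library
#: construct.
SECM_CONTEXT = "TTCAGCACGCCCGTCTGG"

_DNA_BASES = "ACGT"


class InvalidPeptideError(ValueError):
    """A peptide fails the alphabet/length contract."""


class MissingCodonError(KeyError):
    """A residue has no codon in the supplied codon-usage table."""


def validate_peptide(peptide: str, length: int = PEPTIDE_LENGTH) -> str:
    if not isinstance(peptide, str) or len(peptide) != length:
        raise InvalidPeptideError(
            f"peptide must be a string of length {length}, got {peptide!r}"
        )
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise InvalidPeptideError(
            f"peptide {peptide!r} contains non-standard residues {sorted(bad)}"
        )
    return peptide


def enumerate_tetrapeptides(
    alphabet: str = AMINO_ACIDS, length: int = PEPTIDE_LENGTH
) -> list[str]:
    """Enumerate every peptide of the given length over ``alphabet``.

    Returns the sequences in lexicographic order of the (sorted) alphabet, so
    the full design space of 20**4 = 160,000 tetrapeptides has a stable,
    documented ordering.
    """
    letters = sorted(set(alphabet))
    return ["".join(t) for t in itertools.product(letters, repeat=length)]


def translate_dna(dna: str) -> str:
    """Translate a DNA string with the standard genetic code ('*' for stop)."""
    if len(dna) % 3:
        raise ValueError(f"DNA length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())


@dataclass(frozen=True)
class NNKReport:
    """The 32-codon NNK set and what it encodes.

    N = {A,C,G,T} at codon positions 1-2 and K = {G,T} at position 3.  The set
    covers all 20 amino acids; its only stop codon is TAG (amber).
    """

    codons: tuple[str, ...]
    amino_acids: frozenset[str]
    stop_codons: tuple[str, ...]
    codons_by_aa: Mapping[str, tuple[str, ...]] = field(repr=False, default=None)


def nnk_codon_set() -> NNKReport:
    codons = tuple(
        a + b + c for a in _DNA_BASES for b in _DNA_BASES for c in "GT"
    )
    by_aa: dict[str, list[str]] = {}
    stops = []
    for codon in codons:
        aa = translate_dna(codon)
        if aa == "*":
            stops.append(codon)
        else:
            by_aa.setdefault(aa, []).append(codon)
    return NNKReport(
        codons=codons,
        amino_acids=frozenset(by_aa),
        stop_codons=tuple(sorted(stops)),
        codons_by_aa={aa: tuple(sorted(cs)) for aa, cs in by_aa.items()},
    )


class CodonUsageTable:
    """Per-amino-acid codons with CAI-style relative adaptiveness weights.

    Weights are in [0, 1] with the most frequent synonymous codon at 1.0
    (w = f / max f within each amino acid).  Reverse translation picks the
    maximum-weight codon, breaking exact ties alphabetically.
    """

    def __init__(self, weights: Mapping[str, Iterable[tuple[str, float]]]):
        self._weights: dict[str, list[tuple[str, float]]] = {}
        for aa, entries in weights.items():
            entries = sorted(entries)  # alphabetical codon order fixes ties
            if not entries:
                raise ValueError(f"amino acid {aa!r} has no codons")
            for codon, w in entries:
                if len(codon) != 3 or set(codon) - set(_DNA_BASES):
                    raise ValueError(f"invalid codon {codon!r} for {aa!r}")
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"weight {w} for {codon} outside [0, 1]")
            top = max(w for _, w in entries)
            if abs(top - 1.0) > 1e-9:
                raise ValueError(
                    f"weights for {aa!r} must have max 1.0, got {top}"
                )
            self._weights[aa] = entries

    @classmethod
    def from_frequencies(
        cls, freqs: Mapping[str, tuple[str, float]]
    ) -> "CodonUsageTable":
        """Build from {codon: (amino_acid, frequency)}; stops ('*') dropped."""
        by_aa: dict[str, list[tuple[str, float]]] = {}
        for codon, (aa, f) in freqs.items():
            if aa == "*":
                continue
            by_aa.setdefault(aa, []).append((codon, float(f)))
        weights = {
            aa: [(c, f / max(f2 for _, f2 in cs)) for c, f in cs]
            for aa, cs in by_aa.items()
        }
        return cls(weights)

    @classmethod
    def load(cls, path=None) -> "CodonUsageTable":
        """Load the bundled E. coli K-12 usage table (or a TSV like it)."""
        if path is None:
            ref = resources.files("teploop.data") / "codon_usage_ecoli.tsv"
            text = ref.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        freqs: dict[str, tuple[str, float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("codon\t"):
                continue
            codon, aa, f = line.split("\t")
            freqs[codon] = (aa, float(f))
        return cls.from_frequencies(freqs)

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(self._weights)

    def codons_for(self, aa: str) -> list[tuple[str, float]]:
        try:
            return list(self._weights[aa])
        except KeyError:
            raise MissingCodonError(f"no codons for residue {aa!r}") from None

    def optimal_codon(self, aa: str) -> str:
        entries = self.codons_for(aa)
        # max weight; ties resolved by the alphabetical ordering set in __init__
        return max(entries, key=lambda cw: cw[1])[0]


def reverse_translate_cai(peptide: str, table: CodonUsageTable) -> str:
    """Map a peptide to DNA using the CAI-optimal codon for each residue."""
    validate_peptide(peptide, length=len(peptide))
    return "".join(table.optimal_codon(aa) for aa in peptide)


@dataclass(frozen=True)
class OrfPrefix:
    """The 33-nt / 11-codon ORF prefix whose mRNA ensemble energy is a feature.

    Layout: start codon (ATG) + 12-nt randomized region + the fixed 18-nt SecM
    context (:data:`SECM_CONTEXT`).
    """

    dna: str
    peptide: str

    def __post_init__(self):
        if len(self.dna) != 33:
            raise ValueError(f"ORF prefix must be 33 nt, got {len(self.dna)}")
        if not self.dna.startswith(START_CODON):
            raise ValueError("ORF prefix must start with ATG")
        if not self.dna.endswith(SECM_CONTEXT):
            raise ValueError("ORF prefix must end with the SecM context")

    @property
    def codons(self) -> list[str]:
        return [self.dna[i : i + 3] for i in range(0, len(self.dna), 3)]

    @property
    def randomized_region(self) -> str:
        return self.dna[3:15]


def build_orf_prefix(peptide: str, table: CodonUsageTable) -> OrfPrefix:
    validate_peptide(peptide)
    dna = START_CODON + reverse_translate_cai(peptide, table) + SECM_CONTEXT
    return OrfPrefix(dna=dna, peptide=peptide)
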