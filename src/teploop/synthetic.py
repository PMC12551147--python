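"""Synthetic activity landscapes, noisy measurements, and simulated reads.

No experimental fluorescence table is deposited with the study this package
operationalizes, so every pipeline stage is exercised against a synthetic
stand-in for the CFPS measurements.  The generator emulates the measurement
structure of the real campaign:

* a hidden ground-truth activity over all 160,000 tetrapeptides, built from a
  sparse linear combination of standardized descriptor features passed
  through an exponential (right-skewing) transform — highly active peptides
  are rare, most of the mass sits at low activity;
* an injected positional bonus (default: aspartate at peptide position 4,
  +0.6 on the score scale) mirroring the D-at-position-4 enrichment seen in
  the screening;
* triplicate measurements with additive Gaussian noise, reported as the
  replicate mean and SD, normalized so the SKIK reference is exactly 1;
* NNK-amplicon read simulation for the extraction module.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .activity import ActivityTable
from .descriptors import (
    DescriptorScale,
    descriptor_matrix,
    load_scales,
)
from .sequence_space import (
    AMINO_ACIDS,
    PEPTIDE_LENGTH,
    SECM_CONTEXT,
    enumerate_tetrapeptides,
    nnk_codon_set,
    validate_peptide,
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Position rule: (residue, 1-based peptide position, additive score bonus).
BonusRule = tuple[str, int, float]


@dataclass(frozen=True)
class LandscapeSpec:
    """Ground-truth landscape parameters (the study conditions).

    ``sparsity`` is the fraction of the 104 positional descriptor features
    (26 components x 4 variable positions) given a nonzero ground-truth
    weight; weights are rescaled so the latent score has SD
    ``target_score_sd`` over uniformly random peptides.  The activity is
    exp(skew_alpha * (score + bonuses)), normalized so the reference peptide
    maps to 1; ``transform="softplus"`` is a milder alternative.  Measurement
    noise is additive Gaussian per replicate on the relative-activity scale.
    """

    sparsity: float = 0.05
    target_score_sd: float = 0.4
    bonus_rules: tuple[BonusRule, ...] = (("D", 4, 0.6),)
    transform: str = "exp"
    skew_alpha: float = 1.0
    reference: str = "SKIK"
    noise_sd: float = 0.1
    replicates: int = 3
    seed: int = 2024

    def __post_init__(self):
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.transform not in ("exp", "softplus"):
            raise ValueError("transform must be 'exp' or 'softplus'")
        for res, pos, _ in self.bonus_rules:
            if res not in AMINO_ACIDS or not 1 <= pos <= PEPTIDE_LENGTH:
                raise ValueError(f"invalid bonus rule ({res}, {pos})")


class SyntheticOracle:
    """Hidden true-activity function plus a measurement sampler.

    Callable with ``(peptides, seed)`` so it satisfies the design-loop oracle
    contract interchangeably with a lab-results file.
    """

    def __init__(self, spec: LandscapeSpec, scales: Optional[Mapping[str, DescriptorScale]] = None):
        self.spec = spec
        scales = scales if scales is not None else load_scales()
        D = descriptor_matrix(scales)  # (20, 26)
        mu = D.mean(axis=0)
        sd = D.std(axis=0)
        self._zD = (D - mu) / sd  # standardized components over the alphabet

        rng = np.random.default_rng(spec.seed)
        n_feats = self._zD.shape[1] * PEPTIDE_LENGTH
        k = max(1, round(spec.sparsity * n_feats))
        flat = rng.choice(n_feats, size=k, replace=False)
        W = np.zeros((self._zD.shape[1], PEPTIDE_LENGTH))
        W[flat % self._zD.shape[1], flat // self._zD.shape[1]] = rng.normal(size=k)
        # exact score variance over uniform residues: positions independent,
        # components within a position covary through the shared residue draw
        var = 0.0
        for pos in range(PEPTIDE_LENGTH):
            contrib = self._zD @ W[:, pos]  # value per residue
            var += contrib.var()
        if var > 0:
            W *= spec.target_score_sd / math.sqrt(var)
        self._W = W

        ref_score = self._raw_scores([spec.reference])[0]
        self._ref_transformed = self._transform(np.array([ref_score]))[0]
        if not self._ref_transformed > 0:
            raise ValueError("reference peptide maps to non-positive activity")

    def _raw_scores(self, peptides: Sequence[str]) -> np.ndarray:
        idx = np.empty((len(peptides), PEPTIDE_LENGTH), dtype=np.intp)
        for i, p in enumerate(peptides):
            validate_peptide(p)
            for j, aa in enumerate(p):
                idx[i, j] = _AA_INDEX[aa]
        score = np.zeros(len(peptides))
        for pos in range(PEPTIDE_LENGTH):
            score += self._zD[idx[:, pos]] @ self._W[:, pos]
        for res, pos, delta in self.spec.bonus_rules:
            score += np.where(idx[:, pos - 1] == _AA_INDEX[res], delta, 0.0)
        return score

    def _transform(self, score: np.ndarray) -> np.ndarray:
        if self.spec.transform == "exp":
            return np.exp(self.spec.skew_alpha * score)
        return np.log1p(np.exp(self.spec.skew_alpha * score))

    def true_activity(self, peptides: Sequence[str]) -> np.ndarray:
        """Noise-free relative activity (reference = 1) for each peptide."""
        return self._transform(self._raw_scores(peptides)) / self._ref_transformed

    def measure(
        self,
        peptides: Sequence[str],
        seed: int,
        round_label: int = 0,
        replicates: Optional[int] = None,
    ) -> ActivityTable:
        """Simulated CFPS measurement: replicate mean with SD, SKIK-relative.

        Negative replicate draws are clipped at zero (fluorescence cannot be
        negative), so measured means are always >= 0.
        """
        reps = replicates if replicates is not None else self.spec.replicates
        true = self.true_activity(peptides)
        rng = np.random.default_rng([seed, self.spec.seed])
        draws = true[:, None] + rng.normal(0.0, self.spec.noise_sd, (true.size, reps))
        draws = np.clip(draws, 0.0, None)
        mean = draws.mean(axis=1)
        sd = draws.std(axis=1, ddof=1) if reps > 1 else np.zeros(true.size)
        return ActivityTable.from_records(
            [
                {
                    "peptide": p,
                    "raw_intensity": m,
                    "relative_intensity": m,
                    "replicate_sd": s,
                    "source": "synthetic",
                    "round": round_label,
                }
                for p, m, s in zip(peptides, mean, sd)
            ],
            normalized=True,
        )

    def __call__(self, peptides: Sequence[str], seed: int, round_label: int = 0) -> ActivityTable:
        return self.measure(peptides, seed, round_label=round_label)


def make_landscape(
    spec: Optional[LandscapeSpec] = None,
    scales: Optional[Mapping[str, DescriptorScale]] = None,
) -> SyntheticOracle:
    """Build the hidden ground-truth oracle for a landscape spec."""
    return SyntheticOracle(spec if spec is not None else LandscapeSpec(), scales)


def initial_screening_table(
    oracle: SyntheticOracle,
    seed: int,
    n_total: int = 158,
    n_screen: int = 3000,
    n_top: int = 100,
    round_label: int = 0,
    alphabet: str = AMINO_ACIDS,
) -> ActivityTable:
    """Emulate the in vivo screen that seeds round-1 training.

    ``n_screen`` random distinct peptides get a single noisy screening read;
    the ``n_top`` brightest plus a random filler (all positives and "some
    clones with lower fluorescence") are re-measured in triplicate together
    with the reference peptide, giving ``n_total`` training records with the
    reference included.
    """
    rng = np.random.default_rng([seed, 7])
    space = enumerate_tetrapeptides(alphabet=alphabet)
    n_screen = min(n_screen, len(space))
    picked = rng.choice(len(space), size=n_screen, replace=False)
    candidates = [space[i] for i in picked if space[i] != oracle.spec.reference]
    screened = oracle.measure(candidates, seed=int(rng.integers(2**31)), replicates=1)
    order = np.argsort(-screened.df["relative_intensity"].to_numpy())
    n_top = min(n_top, n_total - 1)
    chosen = [candidates[i] for i in order[:n_top]]
    rest = [candidates[i] for i in order[n_top:]]
    n_fill = n_total - 1 - len(chosen)
    if n_fill > 0:
        fill_idx = rng.choice(len(rest), size=min(n_fill, len(rest)), replace=False)
        chosen.extend(rest[i] for i in sorted(fill_idx))
    chosen.append(oracle.spec.reference)
    return oracle.measure(chosen, seed=int(rng.integers(2**31)), round_label=round_label)


# --- NNK amplicon read simulation -----------------------------------------

#: Upstream amplicon sequence ending right before the start codon.
_UPSTREAM = "AAGAAGGAGATATACAT"
#: Synthetic downstream filler past the fixed SecM context so 81-bp reads are
#: fully covered; plausible coding sequence, not taken from any real construct.
_DOWNSTREAM_FILLER = "ATAAGCCAGGCGCAAGGCATTCGTGCGGGTCCGGCACTGGAAGATCTGTAT"


def simulate_reads(
    pool: Mapping[str, float] | Sequence[str],
    n_reads: int,
    read_len: int = 81,
    seed: int = 0,
    error_rate: float = 0.0,
    offset_range: int = 0,
) -> list[tuple[str, str, str]]:
    """Simulate single-end reads over the randomized-region amplicon.

    ``pool`` maps peptides to relative abundances (a plain sequence means
    uniform).  Each read embeds the upstream flank, the start codon, an
    NNK-conformant codon choice for the peptide (uniform over each residue's
    NNK codons), and the downstream SecM context, optionally shifted by a
    random offset of up to ``offset_range`` extra upstream bases.
    Substitution errors are applied uniformly at ``error_rate`` per base.
    Returns (read id, sequence, quality) triples.
    """
    if isinstance(pool, Mapping):
        peptides = list(pool)
        weights = np.asarray([pool[p] for p in peptides], dtype=float)
    else:
        peptides = list(pool)
        weights = np.ones(len(peptides))
    if not peptides:
        raise ValueError("peptide pool must be non-empty")
    for p in peptides:
        validate_peptide(p)
    weights = weights / weights.sum()

    nnk = nnk_codon_set().codons_by_aa
    rng = np.random.default_rng(seed)
    template_tail = SECM_CONTEXT + _DOWNSTREAM_FILLER
    bases = np.array(list("ACGT"))
    reads = []
    choices = rng.choice(len(peptides), size=n_reads, p=weights)
    for i in range(n_reads):
        p = peptides[choices[i]]
        region = "".join(nnk[aa][rng.integers(len(nnk[aa]))] for aa in p)
        pad = "".join(bases[rng.integers(4, size=rng.integers(offset_range + 1))]) if offset_range else ""
        full = pad + _UPSTREAM + "ATG" + region + template_tail
        seq = full[:read_len]
        if error_rate > 0:
            arr = np.array(list(seq))
            hits = rng.random(arr.size) < error_rate
            if hits.any():
                arr[hits] = bases[rng.integers(4, size=int(hits.sum()))]
            seq = "".join(arr)
        reads.append((f"read_{i}", seq, "I" * len(seq)))
    return reads


def write_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
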