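"""Recover tetrapeptide identities from NNK-amplicon short reads.

Negative clones are pooled and their 161-bp randomized-region amplicon is
sequenced with 81-bp single-end reads, so extraction anchors on the short
internal flanks rather than the full primers: the 12-nt randomized region
lies between the upstream anchor ending in CATATG (the start codon closes
the anchor) and the downstream anchor TTCAGCACG (start of the SecM context).
Failures are reported as statuses, never exceptions, and tallies conserve
reads: ok counts + failure counts = input reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

from .sequence_space import translate_dna

UP_FLANK = "CATATG"
DOWN_FLANK = "TTCAGCACG"
REGION_LENGTH = 12

STATUSES = ("ok", "flank_missing", "bad_length", "contains_stop", "ambiguous_base")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: Optional[str] = None


@dataclass(frozen=True)
class ExtractionResult:
    read_id: str
    status: str
    peptide: Optional[str] = None
    dna_region: Optional[str] = None


def _find_anchor(seq: str, anchor: str, start: int, max_mismatch: int) -> int:
    """Index of the first anchor occurrence at or after ``start``, else -1."""
    if max_mismatch == 0:
        return seq.find(anchor, start)
    m = len(anchor)
    for i in range(start, len(seq) - m + 1):
        mism = 0
        for a, b in zip(seq[i : i + m], anchor):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return i
    return -1


def translate_region(dna: str) -> tuple[Optional[str], str]:
    """Translate a 12-nt region; returns (peptide | None, status)."""
    if len(dna) % 3:
        raise ValueError(f"region length {len(dna)} is not a multiple of 3")
    peptide = translate_dna(dna)
    if "*" in peptide:
        return None, "contains_stop"
    return peptide, "ok"


def extract_randomized_region(
    read: ReadRecord,
    up_flank: str = UP_FLANK,
    down_flank: str = DOWN_FLANK,
    max_mismatch: int = 0,
) -> ExtractionResult:
    """Pull the 12-nt randomized region out of one read and translate it.

    Anchors match exactly by default; ``max_mismatch=1`` tolerates one
    substitution per anchor.  Extraction is position-independent: arbitrary
    bases upstream of the anchor do not change the result.
    """
    seq = read.sequence.upper()
    up = _find_anchor(seq, up_flank, 0, max_mismatch)
    if up < 0:
        return ExtractionResult(read.id, "flank_missing")
    region_start = up + len(up_flank)
    down = _find_anchor(seq, down_flank, region_start, max_mismatch)
    if down < 0:
        return ExtractionResult(read.id, "flank_missing")
    region = seq[region_start:down]
    if len(region) != REGION_LENGTH:
        return ExtractionResult(read.id, "bad_length", dna_region=region)
    if set(region) - set("ACGT"):
        return ExtractionResult(read.id, "ambiguous_base", dna_region=region)
    peptide, status = translate_region(region)
    return ExtractionResult(read.id, status, peptide=peptide, dna_region=region)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (gzip transparently handled)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                quality="".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                ),
            )


def extract_fastq(
    path,
    up_flank: str = UP_FLANK,
    down_flank: str = DOWN_FLANK,
    max_mismatch: int = 0,
    min_quality: Optional[float] = None,
) -> list[ExtractionResult]:
    """Extract every read of a FASTQ file; optional mean-quality filter."""
    results = []
    for read in read_fastq(path):
        if min_quality is not None and read.quality:
            mean_q = sum(ord(c) - 33 for c in read.quality) / len(read.quality)
            if mean_q < min_quality:
                results.append(ExtractionResult(read.id, "flank_missing"))
                continue
        results.append(
            extract_randomized_region(read, up_flank, down_flank, max_mismatch)
        )
    return results


def tally_peptides(
    results: Iterable[ExtractionResult],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count recovered peptides and summarize failures.

    Returns (counts, failures): counts has columns (peptide, count) sorted by
    descending count then lexicographic peptide; failures maps each non-ok
    status to its read count.  Sum of counts plus failures equals the number
    of results.
    """
    counts: dict[str, int] = {}
    failures = {s: 0 for s in STATUSES if s != "ok"}
    for res in results:
        if res.status == "ok":
            counts[res.peptide] = counts.get(res.peptide, 0) + 1
        else:
            failures[res.status] += 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["peptide", "count"],
    )
    return table, failures
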