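"""Peptide-activity tables: normalization, deduplication and labelling.

Activities are sfGFP fluorescence readouts of the XXXX-SecM-sfGFP reporter.
All values used for modelling are expressed relative to the SKIK reference
tetrapeptide (SKIK = 1).  Tables may come from in vivo colony screening,
in vitro (CFPS) measurement, or the synthetic oracle; each record carries its
provenance (source, campaign round, replicate SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

ACTIVITY_COLUMNS = [
    "peptide",
    "raw_intensity",
    "relative_intensity",
    "replicate_sd",
    "source",
    "round",
]

SOURCES = {"in_vivo", "in_vitro", "synthetic"}
REFERENCE_PEPTIDE = "SKIK"


class NormalizationError(ValueError):
    """Reference record missing, duplicated, or zero."""


@dataclass
class ActivityTable:
    """An ordered collection of peptide-activity records.

    Thin wrapper around a DataFrame with the fixed :data:`ACTIVITY_COLUMNS`
    schema plus a normalization flag.  Peptide entries are 4-residue sequences
    or reference labels such as "SKIK"/"no_peptide".
    """

    df: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        missing = [c for c in ACTIVITY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"activity table missing columns {missing}")
        self.df = self.df[ACTIVITY_COLUMNS].reset_index(drop=True)
        raw = self.df["raw_intensity"].to_numpy(dtype=float)
        if np.any(raw[np.isfinite(raw)] < 0):
            raise ValueError("raw_intensity must be >= 0")
        rel = self.df["relative_intensity"].to_numpy(dtype=float)
        if np.any(rel[np.isfinite(rel)] < 0):
            raise ValueError("relative_intensity must be >= 0")

    def __len__(self):
        return len(self.df)

    @property
    def peptides(self) -> list[str]:
        return list(self.df["peptide"])

    @classmethod
    def from_records(
        cls,
        records: Iterable[dict],
        normalized: bool = False,
    ) -> "ActivityTable":
        df = pd.DataFrame(list(records))
        for col, default in (
            ("raw_intensity", np.nan),
            ("relative_intensity", np.nan),
            ("replicate_sd", np.nan),
            ("source", "in_vitro"),
            ("round", 0),
        ):
            if col not in df.columns:
                df[col] = default
        return cls(df=df, normalized=normalized)

    @classmethod
    def read_csv(cls, path, normalized: bool = False) -> "ActivityTable":
        df = pd.read_csv(path)
        missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(df=df, normalized=normalized)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def concat(self, other: "ActivityTable") -> "ActivityTable":
        if self.normalized != other.normalized:
            raise ValueError("cannot concatenate normalized with unnormalized")
        return ActivityTable(
            df=pd.concat([self.df, other.df], ignore_index=True),
            normalized=self.normalized,
        )


def normalize_to_reference(
    table: ActivityTable, reference: str = REFERENCE_PEPTIDE
) -> ActivityTable:
    """Divide every raw intensity by the reference's, which becomes 1.0.

    Idempotent: normalizing an already-normalized table leaves it unchanged
    (the reference's relative intensity is 1 after the first pass).
    """
    df = table.df.copy()
    if table.normalized:
        base = df.loc[df["peptide"] == reference, "relative_intensity"]
        source_col = "relative_intensity"
    else:
        base = df.loc[df["peptide"] == reference, "raw_intensity"]
        source_col = "raw_intensity"
    if len(base) != 1:
        raise NormalizationError(
            f"expected exactly one {reference!r} record, found {len(base)}"
        )
    ref_value = float(base.iloc[0])
    if not (np.isfinite(ref_value) and ref_value > 0):
        raise NormalizationError(f"{reference!r} intensity must be > 0")
    values = df[source_col].to_numpy(dtype=float)
    df["relative_intensity"] = values / ref_value
    sd = df["replicate_sd"].to_numpy(dtype=float)
    if not table.normalized:
        df["replicate_sd"] = sd / ref_value
    return ActivityTable(df=df, normalized=True)


def deduplicate_average(table: ActivityTable, by: str = "sequence") -> ActivityTable:
    """Collapse duplicate peptides into one record with the mean intensity.

    ``by="sequence"`` (default) treats records with the same sequence as
    duplicates; ``by="composition"`` pools records whose residue multisets
    match (position information is lost, so logos should not be computed on a
    composition-pooled table).  The merged record keeps the mean raw and
    relative intensity, the mean replicate SD, the earliest round, the first
    source, and an ``n_merged`` count.
    """
    if by not in ("sequence", "composition"):
        raise ValueError("by must be 'sequence' or 'composition'")
    df = table.df.copy()
    key = (
        df["peptide"]
        if by == "sequence"
        else df["peptide"].map(lambda p: "".join(sorted(p)))
    )
    grouped = df.groupby(key, sort=False)
    out = grouped.agg(
        peptide=("peptide", "first"),
        raw_intensity=("raw_intensity", "mean"),
        relative_intensity=("relative_intensity", "mean"),
        replicate_sd=("replicate_sd", "mean"),
        source=("source", "first"),
        round=("round", "min"),
    ).reset_index(drop=True)
    out["n_merged"] = grouped.size().to_numpy()
    result = ActivityTable(df=out, normalized=table.normalized)
    result.df["n_merged"] = out["n_merged"]
    return result


def classify_positive(
    table: ActivityTable, threshold: float = 1.0
) -> pd.Series:
    """Label records whose activity surpasses the reference (strictly > 1).

    Requires a normalized table; equality with the reference is negative (the
    reference itself is never its own superior).
    """
    if not table.normalized:
        raise ValueError("classify_positive requires a normalized table")
    rel = table.df["relative_intensity"].astype(float)
    labels = rel > threshold
    labels.name = "positive"
    return labels
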