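import numpy as np
import pandas as pd
import pytest

from teploop.activity import (
    ActivityTable,
    NormalizationError,
    classify_positive,
    deduplicate_average,
    normalize_to_reference,
)

from conftest import random_peptides


def make_table(rows, normalized=False):
    return ActivityTable.from_records(rows, normalized=normalized)


class TestNormalization:
    def test_screening_worked_example(self):
        # no-peptide control read 16 against a SKIK reference of 86
        table = make_table(
            [
                {"peptide": "no_peptide", "raw_intensity": 16.0},
                {"peptide": "SKIK", "raw_intensity": 86.0},
            ]
        )
        out = normalize_to_reference(table)
        rel = dict(zip(out.df["peptide"], out.df["relative_intensity"]))
        assert rel["no_peptide"] == pytest.approx(16 / 86)
        assert rel["SKIK"] == pytest.approx(1.0)

    def test_reference_becomes_exactly_one(self):
        table = make_table([{"peptide": "SKIK", "raw_intensity": 86.0}])
        out = normalize_to_reference(table)
        assert out.df["relative_intensity"].iloc[0] == 1.0
        assert out.normalized

    def test_missing_reference_raises(self):
        table = make_table([{"peptide": "AAAA", "raw_intensity": 5.0}])
        with pytest.raises(NormalizationError):
            normalize_to_reference(table)

    def test_duplicate_reference_raises(self):
        table = make_table(
            [
                {"peptide": "SKIK", "raw_intensity": 86.0},
                {"peptide": "SKIK", "raw_intensity": 80.0},
            ]
        )
        with pytest.raises(NormalizationError):
            normalize_to_reference(table)

    def test_zero_reference_raises(self):
        table = make_table([{"peptide": "SKIK", "raw_intensity": 0.0}])
        with pytest.raises(NormalizationError):
            normalize_to_reference(table)

    def test_idempotent(self):
        table = make_table(
            [
                {"peptide": "SKIK", "raw_intensity": 86.0},
                {"peptide": "VSVD", "raw_intensity": 111.8},
            ]
        )
        once = normalize_to_reference(table)
        twice = normalize_to_reference(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestDeduplication:
    def test_mean_of_duplicates(self):
        table = make_table(
            [
                {"peptide": "VSVD", "relative_intensity": 1.0},
                {"peptide": "VSVD", "relative_intensity": 1.2},
            ],
            normalized=True,
        )
        out = deduplicate_average(table)
        assert len(out) == 1
        assert out.df["relative_intensity"].iloc[0] == pytest.approx(1.1)
        assert out.df["n_merged"].iloc[0] == 2

    def test_no_duplicates_is_identity(self, rng):
        peptides = list(dict.fromkeys(random_peptides(rng, 30)))
        table = make_table(
            [{"peptide": p, "relative_intensity": i * 0.1} for i, p in enumerate(peptides)],
            normalized=True,
        )
        out = deduplicate_average(table)
        assert out.peptides == peptides

    def test_planted_collision_structure(self, rng):
        # 217 records built from a known set of 157 distinct sequences,
        # echoing the screening's duplicate accounting
        uniques = list(dict.fromkeys(random_peptides(rng, 400)))[:157]
        extras = [uniques[i % 40] for i in range(60)]
        records = [
            {"peptide": p, "relative_intensity": float(rng.uniform(0, 2))}
            for p in uniques + extras
        ]
        table = make_table(records, normalized=True)
        assert len(table) == 217
        out = deduplicate_average(table)
        assert len(out) == 157
        assert set(out.peptides) == set(uniques)

    def test_weighted_mean_is_preserved(self, rng):
        peptides = random_peptides(rng, 50) * 2
        values = rng.uniform(0, 3, size=len(peptides))
        table = make_table(
            [
                {"peptide": p, "relative_intensity": v}
                for p, v in zip(peptides, values)
            ],
            normalized=True,
        )
        out = deduplicate_average(table)
        total = (out.df["relative_intensity"] * out.df["n_merged"]).sum()
        assert total == pytest.approx(values.sum())

    def test_composition_mode_pools_anagrams(self):
        table = make_table(
            [
                {"peptide": "SKIK", "relative_intensity": 1.0},
                {"peptide": "KIKS", "relative_intensity": 3.0},
            ],
            normalized=True,
        )
        assert len(deduplicate_average(table)) == 2
        pooled = deduplicate_average(table, by="composition")
        assert len(pooled) == 1
        assert pooled.df["relative_intensity"].iloc[0] == pytest.approx(2.0)


class TestClassification:
    def test_above_reference_is_positive(self):
        table = make_table(
            [{"peptide": "VSVD", "relative_intensity": 1.3}], normalized=True
        )
        assert classify_positive(table).tolist() == [True]

    def test_equality_is_negative(self):
        table = make_table(
            [{"peptide": "SKIK", "relative_intensity": 1.0}], normalized=True
        )
        assert classify_positive(table).tolist() == [False]

    def test_empty_table(self):
        table = ActivityTable(
            df=pd.DataFrame(
                columns=[
                    "peptide",
                    "raw_intensity",
                    "relative_intensity",
                    "replicate_sd",
                    "source",
                    "round",
                ]
            ),
            normalized=True,
        )
        assert classify_positive(table).empty

    def test_monotone_in_intensity(self, rng):
        values = rng.uniform(0, 2, size=40)
        table = make_table(
            [
                {"peptide": f"P{i:03d}", "relative_intensity": v}
                for i, v in enumerate(values)
            ],
            normalized=True,
        )
        before = classify_positive(table)
        bumped = table.df.copy()
        bumped["relative_intensity"] += 0.5
        after = classify_positive(ActivityTable(df=bumped, normalized=True))
        assert not (before & ~after).any()

    def test_requires_normalized(self):
        table = make_table([{"peptide": "AAAA", "raw_intensity": 2.0}])
        with pytest.raises(ValueError):
            classify_positive(table)


class TestRoundTrip:
    def test_csv_round_trip_is_lossless(self, tmp_path, rng):
        table = make_table(
            [
                {
                    "peptide": p,
                    "raw_intensity": float(i),
                    "relative_intensity": float(i) / 10,
                    "replicate_sd": 0.05,
                    "source": "in_vitro",
                    "round": 1,
                }
                for i, p in enumerate(random_peptides(rng, 10), start=1)
            ]
        )
        path = tmp_path / "activity.csv"
        table.to_csv(path)
        back = ActivityTable.read_csv(path)
        pd.testing.assert_frame_equal(table.df, back.df)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            make_table([{"peptide": "AAAA", "raw_intensity": -1.0}])
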