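import math

import numpy as np
import pytest

from teploop.analysis import (
    KD_HYDROPATHY,
    PositionFrequencyMatrix,
    dipeptide_adjacency,
    information_content,
    position_frequency_matrix,
    residue_property_regression,
    top_dipeptides,
)
from teploop.sequence_space import AMINO_ACIDS

from conftest import random_peptides


class TestPositionFrequencyMatrix:
    def test_point_mass(self):
        pfm = position_frequency_matrix(["DDDD", "DDDD"])
        assert pfm.n == 2
        for pos in range(1, 5):
            assert pfm.freqs.loc["D", pos] == 1.0
        np.testing.assert_allclose(pfm.freqs.sum(axis=0), 1.0)

    def test_uniform_random_frequencies(self, rng):
        peptides = random_peptides(rng, 100_000)
        pfm = position_frequency_matrix(peptides)
        assert np.all(np.abs(pfm.freqs.to_numpy() - 0.05) < 0.01)

    def test_columns_sum_to_one(self, rng):
        pfm = position_frequency_matrix(random_peptides(rng, 500))
        np.testing.assert_allclose(pfm.freqs.sum(axis=0), 1.0, atol=1e-9)

    def test_union_is_count_weighted_mixture(self, rng):
        a = random_peptides(rng, 300)
        b = random_peptides(rng, 700)
        fa = position_frequency_matrix(a).freqs
        fb = position_frequency_matrix(b).freqs
        fu = position_frequency_matrix(a + b).freqs
        np.testing.assert_allclose(fu, 0.3 * fa + 0.7 * fb, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix(["SKIK", "SKI"])


class TestInformationContent:
    def test_point_mass_is_log2_20(self):
        pfm = position_frequency_matrix(["DDDD"])
        ic = information_content(pfm)
        np.testing.assert_allclose(ic, math.log2(20), atol=1e-12)

    def test_uniform_column_is_zero(self):
        import pandas as pd

        uniform = pd.DataFrame(
            np.full((20, 1), 0.05), index=list(AMINO_ACIDS), columns=[1]
        )
        pfm = PositionFrequencyMatrix(freqs=uniform, n=20)
        assert information_content(pfm)[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_letter_column_closed_form(self):
        # f = (0.75, 0.25): IC = log2(20) + 0.75 log2 0.75 + 0.25 log2 0.25
        peptides = ["A"] * 3 + ["C"]
        pfm = position_frequency_matrix([p * 4 for p in peptides])
        expected = math.log2(20) + 0.75 * math.log2(0.75) + 0.25 * math.log2(0.25)
        assert information_content(pfm)[0] == pytest.approx(expected)

    def test_maximal_iff_point_mass(self, rng):
        mixed = position_frequency_matrix(random_peptides(rng, 50))
        assert np.all(information_content(mixed) < math.log2(20))

    def test_small_sample_correction_reduces_ic(self):
        pfm = position_frequency_matrix(["DDDD"] * 5)
        assert np.all(
            information_content(pfm, small_sample_correction=True)
            <= information_content(pfm)
        )


class TestDipeptideAdjacency:
    def test_single_peptide(self):
        adj = dipeptide_adjacency(["NNDD"])
        assert adj.loc["N", "N"] == 1
        assert adj.loc["N", "D"] == 1
        assert adj.loc["D", "D"] == 1
        assert adj.to_numpy().sum() == 3

    def test_total_is_three_per_peptide(self, rng):
        peptides = random_peptides(rng, 123)
        assert dipeptide_adjacency(peptides).to_numpy().sum() == 3 * 123

    def test_planted_motif_enrichment(self, rng):
        background = random_peptides(rng, 80)
        planted = ["NN" + p[2:] for p in random_peptides(rng, 120)]
        top5 = [pair for pair, _ in top_dipeptides(dipeptide_adjacency(background + planted))]
        assert "NN" in top5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dipeptide_adjacency([])


class TestResiduePropertyRegression:
    def test_identity_relationship(self):
        prop = {aa: float(i) for i, aa in enumerate(AMINO_ACIDS)}
        fit = residue_property_regression(prop, prop)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_inverse_linear(self):
        prop = {aa: float(i) for i, aa in enumerate(AMINO_ACIDS)}
        activity = {aa: -2.0 * v + 5.0 for aa, v in prop.items()}
        fit = residue_property_regression(activity, prop)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_pairs_have_low_r2(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            residues = list(AMINO_ACIDS)
            act = {aa: float(v) for aa, v in zip(residues, rng.normal(size=20))}
            prop = {aa: float(v) for aa, v in zip(residues, rng.normal(size=20))}
            if residue_property_regression(act, prop).r_squared < 0.3:
                low += 1
        assert low >= 16  # independent n=20 pairs rarely reach R^2 of 0.3

    def test_affine_property_rescaling_preserves_r2(self):
        rng = np.random.default_rng(1)
        act = {aa: float(v) for aa, v in zip(AMINO_ACIDS, rng.normal(size=20))}
        fit1 = residue_property_regression(act, KD_HYDROPATHY)
        rescaled = {aa: 3.0 * v - 7.0 for aa, v in KD_HYDROPATHY.items()}
        fit2 = residue_property_regression(act, rescaled)
        assert fit1.r_squared == pytest.approx(fit2.r_squared)

    def test_zero_variance_property_flagged(self):
        act = {"A": 1.0, "C": 2.0, "D": 3.0}
        prop = {"A": 5.0, "C": 5.0, "D": 5.0}
        fit = residue_property_regression(act, prop)
        assert fit.degenerate

    def test_too_few_shared_residues(self):
        with pytest.raises(ValueError):
            residue_property_regression({"A": 1.0, "C": 2.0}, {"A": 0.1, "C": 0.2})


class TestLogoPlot:
    def test_renders_to_file(self, tmp_path, rng):
        pfm = position_frequency_matrix(random_peptides(rng, 40))
        out = tmp_path / "logo.png"
        from teploop.analysis import plot_logo

        plot_logo(pfm, path=out)
        assert out.exists() and out.stat().st_size > 0
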