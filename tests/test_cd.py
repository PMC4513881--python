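"""Rank estimation, MCR-ALS decomposition and component identification."""

import numpy as np
import pytest

from foldbind.cd import SpectraMatrix, estimate_rank, match_components, mcr_als
from foldbind.synthetic import (
    CDScenario,
    gen_cd_titration,
    protein_basis_spectrum_folded,
    protein_basis_spectrum_unfolded,
    rna_basis_spectrum,
)


def reference_library(wl):
    return {
        "unfolded_protein": (wl, protein_basis_spectrum_unfolded(wl)),
        "rna": (wl, rna_basis_spectrum(wl)),
        "folded_protein": (wl, protein_basis_spectrum_folded(wl)),
    }


def known_references(m, p0=8.0):
    """Constraints a real titration provides: the free-protein spectrum is
    the first titration point, the titrant spectrum is measured separately
    and its concentration profile is set by the experimenter."""
    spectra = {0: m.D[0] / p0, 1: rna_basis_spectrum(m.wavelengths)}
    profiles = {1: m.equivalents * p0}
    return dict(known_spectra=spectra, known_profiles=profiles)


class TestEstimateRank:
    def test_rank_one_matrix(self):
        wl = np.arange(200.0, 301.0)
        base = protein_basis_spectrum_unfolded(wl)
        D = np.outer([1.0, 0.5, 0.25, 2.0], base)
        assert estimate_rank(SpectraMatrix(wl, D)) == 1

    def test_noiseless_three_component_mixture(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=0)
        assert estimate_rank(m) == 3

    def test_one_percent_noise_with_known_noise_level(self):
        cfg = CDScenario(noise_sigma_frac=0.01)
        clean, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=11)
        sigma = cfg.noise_sigma_frac * float(np.abs(clean.D).max())
        m, _ = gen_cd_titration(cfg, seed=11)
        assert estimate_rank(m, noise_level=sigma) == 3

    def test_too_few_points_rejected(self):
        wl = np.arange(200.0, 301.0)
        D = np.outer([1.0, 0.5], protein_basis_spectrum_unfolded(wl))
        with pytest.raises(ValueError):
            estimate_rank(SpectraMatrix(wl, D))


class TestMcrAls:
    def test_rank_one_exact_reconstruction(self):
        wl = np.arange(200.0, 301.0)
        base = rna_basis_spectrum(wl)
        D = np.outer([1.0, 0.4, 2.0], base)
        res = mcr_als(SpectraMatrix(wl, D), 1)
        assert res.lof < 1e-8
        assert np.allclose(res.reconstruct(), D, atol=1e-9)

    def test_noiseless_profile_recovery(self):
        m, truth = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=0)
        res = mcr_als(m, 3, **known_references(m), max_iter=3000)
        assert res.lof < 0.1
        for j in range(3):
            best = max(
                abs(np.corrcoef(res.C[:, i], truth["C"][:, j])[0, 1]) for i in range(3)
            )
            assert best > 0.999

    def test_noisy_profile_recovery(self):
        m, truth = gen_cd_titration(CDScenario(noise_sigma_frac=0.01), seed=1)
        res = mcr_als(m, 3, **known_references(m), max_iter=2000)
        for j in range(3):
            best = max(
                abs(np.corrcoef(res.C[:, i], truth["C"][:, j])[0, 1]) for i in range(3)
            )
            assert best > 0.99

    def test_lack_of_fit_monotone(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.01), seed=2)
        res = mcr_als(m, 3, max_iter=200)
        assert np.all(np.diff(res.lof_history) <= 1e-10)

    def test_scale_convention_preserves_product(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=3)
        res = mcr_als(m, 3, max_iter=2000)
        assert np.allclose(res.reconstruct(), m.D, atol=1e-6 * np.abs(m.D).max())
        assert res.C.min() >= 0.0
        assert np.allclose(res.C.max(axis=0), 1.0)

    def test_titration_profiles_monotone(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=4)
        # components 0/1 carry the fixed unfolded-protein / RNA references,
        # so component 2 is the folded species
        res = mcr_als(m, 3, **known_references(m), max_iter=3000)
        unfolded, folded = res.C[:, 0], res.C[:, 2]
        assert np.all(np.diff(unfolded) <= 1e-6 * unfolded.max())
        assert np.all(np.diff(folded) >= -1e-6 * folded.max())

    def test_closure_keeps_protein_sum_constant(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=5)
        res = mcr_als(
            m, 3, **known_references(m), closure=[0, 2], closure_total=8.0,
            max_iter=500,
        )
        totals = res.C[:, 0] + res.C[:, 2]
        assert np.allclose(totals, 8.0, rtol=1e-6)

    def test_bad_component_count_rejected(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.0), seed=0)
        with pytest.raises(ValueError):
            mcr_als(m, 0)
        with pytest.raises(ValueError):
            mcr_als(m, 100)


class TestMatchComponents:
    def test_exact_reference_labeled_with_unit_correlation(self):
        wl = np.arange(200.0, 301.0)
        res = mcr_als(SpectraMatrix(wl, np.outer([1.0, 0.4, 2.0], rna_basis_spectrum(wl))), 1)
        table = match_components(res, reference_library(wl))
        assert table.loc[0, "label"] == "rna"
        assert table.loc[0, "correlation"] == pytest.approx(1.0, abs=1e-9)

    def test_negated_reference_unassigned(self):
        wl = np.arange(200.0, 301.0)
        res = mcr_als(SpectraMatrix(wl, np.outer([1.0, 0.4, 2.0], rna_basis_spectrum(wl))), 1)
        refs = {"neg": (wl, -rna_basis_spectrum(wl))}
        table = match_components(res, refs)
        assert table.loc[0, "label"] is None
        assert table.loc[0, "correlation"] == pytest.approx(-1.0, abs=1e-9)

    def test_three_component_run_labels_all_species(self):
        m, _ = gen_cd_titration(CDScenario(noise_sigma_frac=0.01), seed=1)
        res = mcr_als(m, 3, max_iter=2000)
        table = match_components(res, reference_library(m.wavelengths))
        assert set(table["label"]) == {"unfolded_protein", "rna", "folded_protein"}

    def test_resampling_onto_decomposition_grid(self):
        wl = np.arange(200.0, 301.0)
        res = mcr_als(SpectraMatrix(wl, np.outer([1.0, 0.4, 2.0], rna_basis_spectrum(wl))), 1)
        coarse = np.arange(200.0, 301.0, 5.0)
        table = match_components(res, {"rna": (coarse, rna_basis_spectrum(coarse))})
        assert table.loc[0, "label"] == "rna"
        assert table.loc[0, "correlation"] > 0.999

    def test_disjoint_grid_rejected(self):
        wl = np.arange(200.0, 301.0)
        res = mcr_als(SpectraMatrix(wl, np.outer([1.0, 0.4, 2.0], rna_basis_spectrum(wl))), 1)
        with pytest.raises(ValueError):
            match_components(res, {"x": (np.arange(400.0, 500.0), np.ones(100))})

    def test_empty_library_rejected(self):
        wl = np.arange(200.0, 301.0)
        res = mcr_als(SpectraMatrix(wl, np.outer([1.0, 0.4, 2.0], rna_basis_spectrum(wl))), 1)
        with pytest.raises(ValueError):
            match_components(res, {})


class TestSpectraMatrixValidation:
    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            SpectraMatrix(np.array([300.0, 200.0]), np.ones((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SpectraMatrix(np.arange(200.0, 210.0), np.ones((2, 5)))
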