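"""NMR titration observables: CSPs, exchange-regime predictions, fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldbind.equilibria import ThreeStateModel, solve_species
from foldbind.nmr import (
    RandomCoilTable,
    ShiftTable,
    average_csp_series,
    csp,
    estimate_k2_from_volumes,
    fit_microscopic_kd,
    hetnoe_region_summary,
    predict_intensity_evolution,
    predict_unfolded_shift,
    secondary_shifts,
)
from foldbind.synthetic import DisorderScenario, NMRScenario, gen_nmr_trajectory, gen_shift_tables

finite = st.floats(-2.0, 2.0, allow_nan=False)


class TestCsp:
    def test_closed_form(self):
        assert csp(0.0, 0.0) == 0.0
        assert csp(0.1, 0.6) == pytest.approx(np.sqrt(0.02), rel=1e-12)

    @given(dh=finite, dn=finite)
    @settings(max_examples=200, deadline=None)
    def test_sign_symmetry_and_linear_scaling(self, dh, dn):
        base = csp(dh, dn)
        assert csp(-dh, dn) == pytest.approx(base, rel=1e-12, abs=1e-15)
        assert csp(dh, -dn) == pytest.approx(base, rel=1e-12, abs=1e-15)
        assert csp(3 * dh, 3 * dn) == pytest.approx(3 * base, rel=1e-12, abs=1e-15)


class TestFastExchangeShift:
    def test_limits_and_midpoint(self, study_model):
        at = lambda p, r: solve_species(p, r, study_model)
        free_only = at(100.0, 0.0)
        assert predict_unfolded_shift(free_only, 8.0, 8.5) == 8.0
        # symmetric populations: construct state directly
        from foldbind.equilibria import SpeciesState

        s = SpeciesState(f_u=5.0, r_free=0.0, b_u=5.0, b_f=25.0, p_total=35.0, r_total=30.0)
        assert predict_unfolded_shift(s, 8.0, 8.5) == pytest.approx(8.25)
        s0 = SpeciesState(f_u=0.0, r_free=0.0, b_u=5.0, b_f=25.0, p_total=30.0, r_total=30.0)
        assert predict_unfolded_shift(s0, 8.0, 8.5) == 8.5

    @given(
        r=st.floats(0.0, 2000.0),
        d_free=st.floats(5.0, 12.0),
        d_bound=st.floats(5.0, 12.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_limiting_shifts(self, r, d_free, d_bound):
        s = solve_species(150.0, r, ThreeStateModel(kd1=2.0, k2=5.0))
        out = predict_unfolded_shift(s, d_free, d_bound)
        lo, hi = min(d_free, d_bound), max(d_free, d_bound)
        assert lo - 1e-12 <= out <= hi + 1e-12

    def test_empty_pool_rejected(self):
        from foldbind.equilibria import SpeciesState

        s = SpeciesState(f_u=0.0, r_free=0.0, b_u=0.0, b_f=10.0, p_total=10.0, r_total=10.0)
        with pytest.raises(ValueError):
            predict_unfolded_shift(s, 8.0, 8.5)


class TestAverageCspSeries:
    def test_static_trajectory_gives_zeros(self):
        traj, _ = gen_nmr_trajectory(
            NMRScenario(kd1=1e9, shift_noise_frac=0.0, volume_noise_frac=0.0), seed=0
        )
        series = average_csp_series(traj)
        assert np.allclose(series, 0.0, atol=1e-6)

    def test_matches_closed_form_without_noise(self):
        cfg = NMRScenario(shift_noise_frac=0.0, volume_noise_frac=0.0)
        traj, truth = gen_nmr_trajectory(cfg, seed=1)
        series = average_csp_series(traj)
        model = ThreeStateModel(kd1=cfg.kd1, k2=cfg.k2)
        expected = np.array(
            [
                truth["amplitude_ppm"]
                * solve_species(pt.p_total, pt.r_total, model).unfolded_bound_fraction
                for pt in traj.points
            ]
        )
        assert np.allclose(series, expected, atol=1e-9)

    def test_region_weighting_concentrates_large_csps(self):
        cfg = NMRScenario(shift_noise_frac=0.0, volume_noise_frac=0.0, region_weight=5.0)
        traj, truth = gen_nmr_trajectory(cfg, seed=3)
        per_res = csp(truth["delta_h"], truth["delta_n"])
        residues = truth["residues"]
        in_region = np.zeros(len(residues), bool)
        for start, end in cfg.regions:
            in_region |= (residues >= start) & (residues <= end)
        assert np.median(per_res[in_region]) > 2.0 * np.median(per_res[~in_region])


class TestMicroscopicKdFit:
    def test_noiseless_unconstrained_recovery(self):
        traj, _ = gen_nmr_trajectory(
            NMRScenario(shift_noise_frac=0.0, volume_noise_frac=0.0), seed=2
        )
        fit = fit_microscopic_kd(traj, kd_app=0.3, k2=5.0, mode="unconstrained")
        assert fit.kd1 == pytest.approx(2.0, rel=1e-2)
        assert fit.noise_floor == pytest.approx(0.0, abs=1e-6)

    def test_constrained_mode_fixes_kd1(self):
        traj, _ = gen_nmr_trajectory(NMRScenario(), seed=2)
        fit = fit_microscopic_kd(traj, kd_app=0.3, k2=5.0, mode="constrained")
        assert fit.kd1 == pytest.approx(1.8)
        assert fit.kd1_err == 0.0

    def test_modes_agree_when_truth_matches_constraint(self):
        cfg = NMRScenario(kd1=1.8, shift_noise_frac=0.0, volume_noise_frac=0.0)
        traj, _ = gen_nmr_trajectory(cfg, seed=4)
        con = fit_microscopic_kd(traj, kd_app=0.3, k2=5.0, mode="constrained")
        unc = fit_microscopic_kd(traj, kd_app=0.3, k2=5.0, mode="unconstrained")
        assert unc.kd1 == pytest.approx(con.kd1, rel=1e-3)
        assert unc.amplitude == pytest.approx(con.amplitude, rel=1e-3)

    def test_noisy_median_recovery_within_twenty_percent(self):
        kds = [
            fit_microscopic_kd(
                gen_nmr_trajectory(NMRScenario(), seed=s)[0], kd_app=0.3, k2=5.0
            ).kd1
            for s in range(100)
        ]
        assert abs(np.median(kds) - 2.0) / 2.0 < 0.20

    def test_saturated_design_warns(self):
        # every titrated point far past equivalence: the unfolded pool is
        # fully bound everywhere and kd1 carries no information
        cfg = NMRScenario(
            kd1=0.01, schedule=(0.0, 5.0, 10.0, 15.0, 20.0), shift_noise_frac=0.0,
            volume_noise_frac=0.0,
        )
        traj, _ = gen_nmr_trajectory(cfg, seed=0)
        with pytest.warns(UserWarning, match="saturation"):
            fit_microscopic_kd(traj, kd_app=0.01 / 6, k2=5.0)


class TestK2FromVolumes:
    def test_plain_ratio(self):
        assert estimate_k2_from_volumes(1.0, 5.0) == 5.0
        assert estimate_k2_from_volumes(2.0, 2.0) == 1.0

    def test_corrected_estimator_exact_on_model_volumes(self, study_model):
        for p, r in [(400.0, 500.0), (200.0, 150.0), (50.0, 80.0)]:
            s = solve_species(p, r, study_model)
            vol_u, vol_f = s.f_u + s.b_u, s.b_f
            corrected = estimate_k2_from_volumes(vol_u, vol_f, s)
            assert corrected == pytest.approx(study_model.k2, rel=1e-9)

    def test_naive_close_but_below_at_excess_rna(self, study_model):
        s = solve_species(400.0, 500.0, study_model)
        naive = estimate_k2_from_volumes(s.f_u + s.b_u, s.b_f)
        assert naive == pytest.approx(4.9, abs=0.1)
        assert naive < estimate_k2_from_volumes(s.f_u + s.b_u, s.b_f, s)

    def test_zero_volumes_rejected(self):
        with pytest.raises(ValueError):
            estimate_k2_from_volumes(0.0, 5.0)


class TestIntensityEvolution:
    def test_endpoints_and_monotonicity(self, study_model):
        points = [(200.0, r) for r in np.linspace(0, 800, 30)]
        unfolded, folded = predict_intensity_evolution(points, study_model)
        assert unfolded[0] == pytest.approx(1.0)
        assert folded[0] == 0.0
        assert folded[-1] == pytest.approx(1.0)
        assert np.all(np.diff(unfolded) <= 1e-12)
        assert np.all(np.diff(folded) >= -1e-12)

    def test_saturation_residual_unfolded_fraction(self):
        # at saturating RNA the unfolded pool settles at 1/(1+k2) of the
        # protein: about 1/6 of its zero-RNA value for k2 = 5
        model = ThreeStateModel(kd1=2.0, k2=5.0)
        points = [(200.0, r) for r in [0.0, 1e5]]
        unfolded, folded = predict_intensity_evolution(points, model)
        assert unfolded[-1] == pytest.approx(1.0 / 6.0, abs=5e-3)


class TestSecondaryShifts:
    def test_random_coil_observations_score_zero(self):
        rc = RandomCoilTable.bundled()
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        df = pd.DataFrame(
            {
                "residue": np.arange(len(aa)),
                "aa": aa,
                "dh": 8.2,
                "dn": 119.0,
                "ca": [rc.ca(a) for a in aa],
                "co": [rc.co(a) for a in aa],
            }
        )
        out = secondary_shifts(ShiftTable(df), rc)
        assert np.allclose(out["combined"], 0.0, atol=1e-12)

    def test_helical_offsets_sum(self):
        rc = RandomCoilTable.bundled()
        df = pd.DataFrame(
            {
                "residue": [1, 2],
                "aa": ["A", "L"],
                "dh": 8.2,
                "dn": 119.0,
                "ca": [rc.ca("A") + 3.0, rc.ca("L") + 3.0],
                "co": [rc.co("A") + 2.0, rc.co("L") + 2.0],
            }
        )
        out = secondary_shifts(ShiftTable(df), rc)
        assert np.allclose(out["combined"], 5.0)
        out_mean = secondary_shifts(ShiftTable(df), rc, combine="mean")
        assert np.allclose(out_mean["combined"], 2.5)

    def test_synthetic_c_terminal_propensity_pattern(self):
        table, truth = gen_shift_tables(DisorderScenario(), seed=5)
        rc = RandomCoilTable.bundled()
        out = secondary_shifts(table, rc)
        mid = truth["midpoint"]
        n_half = out[out["residue"] < mid]["combined"].abs().mean()
        c_half = out[out["residue"] >= mid]["combined"].abs().mean()
        assert c_half > 2.0 * n_half

    def test_missing_carbons_skipped(self):
        rc = RandomCoilTable.bundled()
        df = pd.DataFrame(
            {
                "residue": [1, 2],
                "aa": ["A", "L"],
                "dh": 8.2,
                "dn": 119.0,
                "ca": [rc.ca("A"), np.nan],
                "co": [rc.co("A"), 177.0],
            }
        )
        out = secondary_shifts(ShiftTable(df), rc)
        assert list(out["residue"]) == [1]


class TestHetNoe:
    def test_uniform_profile_unflagged(self):
        df = pd.DataFrame(
            {"residue": np.arange(10), "aa": "A", "dh": 8.2, "dn": 119.0, "hetnoe": 0.2}
        )
        out = hetnoe_region_summary(ShiftTable(df), [(0, 4), (5, 9)])
        assert np.allclose(out["mean"], 0.2)
        assert not out["rigid"].any()

    def test_single_residue_region_and_empty_region(self):
        df = pd.DataFrame(
            {"residue": [1, 2, 3], "aa": "A", "dh": 8.2, "dn": 119.0, "hetnoe": [0.1, 0.6, 0.3]}
        )
        out = hetnoe_region_summary(ShiftTable(df), [(2, 2), (10, 20)])
        assert out.loc[0, "mean"] == pytest.approx(0.6)
        assert out.loc[0, "sd"] == 0.0
        assert bool(out.loc[0, "rigid"])
        assert bool(out.loc[1, "empty"])

    def test_synthetic_halves_separate(self):
        table, truth = gen_shift_tables(DisorderScenario(), seed=6)
        mid = truth["midpoint"]
        first = int(table.data["residue"].min())
        last = int(table.data["residue"].max())
        out = hetnoe_region_summary(table, [(first, mid - 1), (mid, last)])
        assert out.loc[1, "mean"] > out.loc[0, "mean"]


class TestShiftTableValidation:
    def test_duplicate_residues_rejected(self):
        df = pd.DataFrame({"residue": [1, 1], "aa": "A", "dh": 8.2, "dn": 119.0})
        with pytest.raises(ValueError, match="duplicate"):
            ShiftTable(df)

    def test_implausible_shifts_flagged_not_fatal(self):
        df = pd.DataFrame({"residue": [1], "aa": ["A"], "dh": [25.0], "dn": [119.0]})
        t = ShiftTable(df)
        assert t.flags
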