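"""Binding models: fraction bound, Hill fits, one-site ITC, FRET."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbescan.binding import (
    GAS_CONSTANT_KJ,
    ITCExperiment,
    OneSiteParams,
    TitrationSeries,
    default_dilution_series,
    fit_hill,
    fit_one_site_itc,
    fraction_bound,
    fret_efficiency,
    hill_model,
    simulate_one_site_itc,
)
from fbescan.simulate import generate_emsa, generate_itc


class TestRatios:
    @pytest.mark.parametrize(
        "bound, unbound, expected",
        [(50, 50, 0.5), (100, 0, 1.0), (30, 70, 0.30)],
    )
    def test_fraction_bound(self, bound, unbound, expected):
        assert fraction_bound(bound, unbound) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "acc, don, expected", [(7.0, 7.0, 0.5), (0, 100, 0.0), (75, 25, 0.75)]
    )
    def test_fret_efficiency(self, acc, don, expected):
        assert fret_efficiency(acc, don) == pytest.approx(expected)

    def test_zero_lane_rejected(self):
        with pytest.raises(ValueError):
            fraction_bound(0, 0)
        with pytest.raises(ValueError):
            fret_efficiency(0, 0)

    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    def test_ratios_in_unit_interval(self, a, b):
        if a + b == 0:
            return
        assert 0.0 <= fraction_bound(a, b) <= 1.0
        assert 0.0 <= fret_efficiency(a, b) <= 1.0


class TestHillModel:
    @pytest.mark.parametrize("h", [0.5, 1.0, 1.5, 3.0])
    def test_half_saturation_identity(self, h):
        assert hill_model(250.0, kd=250.0, h=h, bmax=0.9) == pytest.approx(0.45)

    def test_zero_concentration(self):
        assert hill_model(0.0, kd=100.0, h=1.3, bmax=1.0) == 0.0

    def test_hand_evaluation(self):
        # direct arithmetic: bmax*c^h/(kd^h + c^h) at c=5000, kd=427, h=1.5
        c, kd, h = 5000.0, 427.0, 1.5
        expected = c**h / (kd**h + c**h)
        assert hill_model(c, kd=kd, h=h, bmax=1.0) == pytest.approx(expected, rel=1e-12)
        # 5000^1.5 = 353553.39; 427^1.5 = 8823.60; ratio = 0.975651
        assert expected == pytest.approx(0.975651, abs=1e-6)

    @given(
        kd=st.floats(1.0, 5000.0),
        h=st.floats(0.3, 4.0),
    )
    @settings(max_examples=50)
    def test_monotone_in_concentration(self, kd, h):
        conc = np.linspace(0, 10000, 200)
        f = hill_model(conc, kd=kd, h=h, bmax=1.0)
        assert np.all(np.diff(f) >= -1e-12)


class TestFitHill:
    def test_noiseless_recovery_printed_affinity(self):
        series = generate_emsa(kd=435.0, h=1.3, bmax=1.0, noise_sd=0.0)
        fit = fit_hill(series)
        assert fit.kd_app == pytest.approx(435.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.3, rel=1e-6)
        assert fit.bmax == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_recovery_simple(self):
        series = generate_emsa(kd=100.0, h=1.0, bmax=1.0, noise_sd=0.0)
        fit = fit_hill(series)
        assert fit.kd_app == pytest.approx(100.0, rel=1e-6)

    @given(
        kd=st.floats(20.0, 2000.0),
        h=st.floats(0.7, 2.5),
        bmax=st.floats(0.6, 1.0),
    )
    @settings(max_examples=25)
    def test_round_trip_property(self, kd, h, bmax):
        series = generate_emsa(kd=kd, h=h, bmax=bmax, noise_sd=0.0)
        fit = fit_hill(series)
        assert fit.kd_app == pytest.approx(kd, rel=1e-4)
        assert fit.hill == pytest.approx(h, rel=1e-4)

    def test_noisy_median_recovery(self):
        kds = [
            fit_hill(generate_emsa(kd=427.0, h=1.5, noise_sd=0.02, seed=s)).kd_app
            for s in range(50)
        ]
        assert np.median(kds) == pytest.approx(427.0, rel=0.10)

    def test_all_zero_rejected(self):
        conc = default_dilution_series()
        series = TitrationSeries(conc, np.zeros_like(conc))
        with pytest.raises(Exception):
            fit_hill(series)

    def test_too_few_points_rejected(self):
        series = TitrationSeries(np.array([1.0, 2.0, 4.0]), np.array([0.1, 0.2, 0.4]))
        with pytest.raises(ValueError):
            fit_hill(series)


TABLE1_LINE1 = OneSiteParams(N=0.5, kd_app=1.1, dH=-61.9, temperature=293.15)
GEOMETRY = ITCExperiment(cell_conc=20.0, syringe_conc=300.0)


class TestITC:
    def test_athermal_limit(self):
        heats = simulate_one_site_itc(
            OneSiteParams(N=1.0, kd_app=1.0, dH=0.0), GEOMETRY
        )
        assert np.allclose(heats, 0.0)

    def test_tight_binding_limit(self):
        heats = simulate_one_site_itc(
            OneSiteParams(N=1.0, kd_app=1e-5, dH=-50.0), GEOMETRY
        )
        ratios = GEOMETRY.molar_ratios()
        assert np.allclose(heats[ratios < 0.9], -50.0, atol=0.2)
        assert np.allclose(heats[ratios > 1.15], 0.0, atol=0.2)

    def test_stoichiometry_round_trip(self):
        exp = generate_itc(TABLE1_LINE1, GEOMETRY)
        fit = fit_one_site_itc(exp)
        assert fit.N == pytest.approx(0.5, rel=1e-6)
        assert fit.kd_app == pytest.approx(1.1, rel=1e-6)
        assert fit.dH == pytest.approx(-61.9, rel=1e-6)

    def test_n_equal_one_round_trip(self):
        exp = generate_itc(OneSiteParams(N=1.0, kd_app=2.0, dH=-45.0), GEOMETRY)
        assert fit_one_site_itc(exp).N == pytest.approx(1.0, rel=1e-6)

    def test_inflection_scales_with_stoichiometry(self):
        # the molar-ratio midpoint of the transition doubles from N=0.5 to N=1;
        # many small injections give a fine molar-ratio grid for locating it
        geo = ITCExperiment(
            cell_conc=20.0, syringe_conc=300.0, injection_volume=0.2, n_injections=190
        )
        ratios = geo.molar_ratios()

        def midpoint(n):
            h = simulate_one_site_itc(OneSiteParams(N=n, kd_app=0.01, dH=-50.0), geo)
            return ratios[int(np.argmin(np.abs(h - h[0] / 2)))]

        assert midpoint(1.0) / midpoint(0.5) == pytest.approx(2.0, rel=0.1)

    def test_free_energy_from_printed_kd(self):
        # dG = RT ln Kd with Kd in molar, at 20 C
        dG = GAS_CONSTANT_KJ * 293.15 * np.log(1.1e-6)
        assert TABLE1_LINE1.dG == pytest.approx(dG)
        assert round(TABLE1_LINE1.dG, 1) == -33.4
        assert TABLE1_LINE1.minus_TdS == pytest.approx(TABLE1_LINE1.dG + 61.9)

    def test_heat_conservation_small_injections(self):
        # with a negligible displaced volume (total injected << V0) the sum of
        # per-injection heats approaches the final cumulative heat
        # [MX]_final * dH * V0; a concentrated syringe keeps binding substantial
        params = OneSiteParams(N=1.0, kd_app=1.0, dH=-60.0)
        geo = ITCExperiment(
            cell_conc=20.0,
            syringe_conc=8400.0,
            injection_volume=0.05,
            n_injections=19,
        )
        heats = simulate_one_site_itc(params, geo)  # kJ/mol injectant
        v = geo.injection_volume * 1e-6
        total = np.sum(heats) * geo.syringe_conc * 1e-6 * v  # kJ
        i = geo.n_injections
        f = i * v / (2 * geo.cell_volume * 1e-6)
        M = geo.cell_conc * 1e-6 * (1 - f) / (1 + f)
        X = geo.syringe_conc * 1e-6 * (i * v / (geo.cell_volume * 1e-6)) / (1 + f)
        Kd = params.kd_app * 1e-6
        b = params.N * M + X + Kd
        MX = (b - np.sqrt(b * b - 4 * params.N * M * X)) / 2
        expected = MX * params.dH * geo.cell_volume * 1e-6
        assert total == pytest.approx(expected, rel=0.02)

    @given(
        n=st.floats(0.3, 2.0),
        kd=st.floats(0.1, 5.0),
        dh=st.floats(-120.0, -20.0),
    )
    @settings(max_examples=20)
    def test_round_trip_property(self, n, kd, dh):
        exp = generate_itc(OneSiteParams(N=n, kd_app=kd, dH=dh), GEOMETRY)
        fit = fit_one_site_itc(exp)
        assert fit.N == pytest.approx(n, rel=1e-4)
        assert fit.kd_app == pytest.approx(kd, rel=1e-3)
        assert fit.dH == pytest.approx(dh, rel=1e-4)

    def test_low_c_value_warns(self):
        geo = ITCExperiment(cell_conc=0.5, syringe_conc=300.0)
        exp = generate_itc(OneSiteParams(N=1.0, kd_app=50.0, dH=-50.0), geo)
        with pytest.warns(RuntimeWarning, match="c-value"):
            fit_one_site_itc(exp)

    def test_heats_required_for_fit(self):
        with pytest.raises(ValueError):
            fit_one_site_itc(GEOMETRY)
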