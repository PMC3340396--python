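"""Bio-optics: quanta integration, attenuation fitting, penetration depths,
color ratios, and CDOM absorbance conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riverscape import optics as op
from riverscape import synthetic as syn

H, C, NA = op.PLANCK_H, op.SPEED_OF_LIGHT, op.AVOGADRO


def make_profile(depths, wavelengths, ed):
    return op.SpectralProfile("t", np.asarray(depths), np.asarray(wavelengths),
                              np.asarray(ed, dtype=float))


class TestIntegrateQuanta:
    def test_zero_spectrum_gives_zero(self):
        wl = np.arange(351.0, 751.0, 3.0)
        p = make_profile([0.0], wl, np.zeros((1, wl.size)))
        assert op.integrate_quanta(p, op.DEFAULT_BANDS["par"], 0) == 0.0

    def test_single_bin_matches_closed_form(self):
        wl = np.arange(470.0, 531.0, 3.0)  # includes exactly 500 nm
        ed = np.zeros((1, wl.size))
        ed[0, wl == 500.0] = 1.0
        p = make_profile([0.0], wl, ed)
        got = op.integrate_quanta(p, op.Waveband("b", 470, 530), 0)
        # 1 uW cm-2 nm-1 = 1e-2 W m-2 nm-1; trapezoid of one interior spike = Ed*dl
        expected = 1e-2 * 500e-9 * 3.0 / (H * C * NA) * 1e6
        assert got == pytest.approx(expected, rel=1e-12)

    def test_flat_spectrum_matches_fine_grid_quadrature(self):
        wl = np.arange(351.0, 751.0, 3.0)
        p = make_profile([0.0], wl, np.ones((1, wl.size)))
        got = op.integrate_quanta(p, op.DEFAULT_BANDS["par"], 0)
        fine = np.linspace(400.0, 700.0, 200001)
        oracle = np.trapezoid(1e-2 * fine * 1e-9 / (H * C), fine) / NA * 1e6
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_band_outside_range_rejected(self):
        wl = np.arange(400.0, 700.0, 3.0)
        p = make_profile([0.0], wl, np.ones((1, wl.size)))
        with pytest.raises(ValueError, match="outside measured range"):
            op.integrate_quanta(p, op.Waveband("uv", 300, 400), 0)

    def test_linear_in_ed_and_additive_over_disjoint_bands(self):
        rng = np.random.default_rng(4)
        wl = np.arange(351.0, 751.0, 3.0)
        ed = rng.uniform(0.1, 5.0, (1, wl.size))
        p1 = make_profile([0.0], wl, ed)
        p2 = make_profile([0.0], wl, 3.0 * ed)
        band = op.DEFAULT_BANDS["green"]
        assert op.integrate_quanta(p2, band, 0) == pytest.approx(
            3.0 * op.integrate_quanta(p1, band, 0), rel=1e-12
        )
        # split [520, 565] at a shared grid point: trapezoid is interval-additive
        left = op.Waveband("l", 520, 540)
        right = op.Waveband("r", 540, 565)
        assert op.integrate_quanta(p1, left, 0) + op.integrate_quanta(
            p1, right, 0
        ) == pytest.approx(op.integrate_quanta(p1, band, 0), rel=1e-12)


class TestFitKd:
    def test_noiseless_exponential_recovered_exactly(self):
        wl = np.arange(351.0, 751.0, 3.0)
        z = np.arange(0.0, 3.0, 0.1)
        ed = 100.0 * np.exp(-0.5 * z)[:, None] * np.ones(wl.size)
        res = op.fit_kd(make_profile(z, wl, ed), op.DEFAULT_BANDS["blue"])
        assert res.kd == pytest.approx(0.5, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)
        assert res.valid

    def test_two_point_closed_form_via_three_point_profile(self):
        # z = 0, 1, 2 on an exact exponential with K_d = 0.5
        wl = np.arange(432.0, 504.0, 3.0)
        z = np.array([0.0, 1.0, 2.0])
        ed = 100.0 * np.exp(-0.5 * z)[:, None] * np.ones(wl.size)
        res = op.fit_kd(make_profile(z, wl, ed), op.Waveband("blue", 435, 500))
        assert res.kd == pytest.approx(0.5, abs=1e-12)

    def test_zero_irradiance_depths_dropped_and_counted(self):
        wl = np.arange(432.0, 504.0, 3.0)
        z = np.arange(0.0, 1.0, 0.1)
        ed = 100.0 * np.exp(-2.0 * z)[:, None] * np.ones(wl.size)
        ed[-2:] = 0.0
        res = op.fit_kd(make_profile(z, wl, ed), op.Waveband("blue", 435, 500))
        assert res.n_dropped == 2
        assert res.n_depths == z.size - 2
        assert res.kd == pytest.approx(2.0, abs=1e-12)

    def test_too_few_usable_depths_raises(self):
        wl = np.arange(432.0, 504.0, 3.0)
        ed = np.zeros((4, wl.size))
        ed[0] = 1.0
        with pytest.raises(ValueError, match="positive"):
            op.fit_kd(make_profile([0.0, 0.1, 0.2, 0.3], wl, ed),
                      op.Waveband("blue", 435, 500))

    def test_brightening_profile_flagged_invalid(self):
        wl = np.arange(432.0, 504.0, 3.0)
        z = np.arange(0.0, 1.0, 0.1)
        ed = 100.0 * np.exp(+0.5 * z)[:, None] * np.ones(wl.size)
        res = op.fit_kd(make_profile(z, wl, ed), op.Waveband("blue", 435, 500))
        assert not res.valid
        assert res.kd < 0

    def test_mean_fit_within_one_percent_over_replicates(self):
        cfg = syn.RiverConfig(n_transects=1, stations_per_transect=1,
                              profile_noise_sd=0.05, profile_depth_m=1.98)
        rng = np.random.default_rng(7)
        conc = syn.mix_downstream(syn.generate_network(cfg), cfg)
        fits = []
        for _ in range(200):
            profiles, kd_table = syn.generate_profiles(conc, cfg, rng)
            fits.append(op.fit_kd(profiles[0], op.DEFAULT_BANDS["blue"]).kd)
        truth = kd_table["kd_blue"].iloc[0]
        assert abs(np.mean(fits) - truth) / truth < 0.01


class TestPenetrationAndPhotic:
    @pytest.mark.parametrize("kd, expected", [(4.6, 1.0), (0.46, 10.0), (0.23, 20.0)])
    def test_one_percent_depth(self, kd, expected):
        assert op.penetration_depth_1pct(kd) == pytest.approx(expected)

    def test_z1pct_consistent_with_kd(self):
        res = op.AttenuationResult(band="blue", kd=0.37, r2=1.0, n_depths=10)
        assert res.z1pct * res.kd == pytest.approx(op.Z1PCT_CONSTANT)

    @pytest.mark.parametrize(
        "kd, depth, expected",
        [(0.46, 20.0, 50.0), (0.1, 4.97, 100.0), (4.6, 2.0, 50.0)],
    )
    def test_photic_fraction(self, kd, depth, expected):
        assert op.photic_fraction(kd, depth) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(
        kd=st.floats(0.01, 10.0),
        kd2=st.floats(0.01, 10.0),
        depth=st.floats(0.1, 100.0),
        depth2=st.floats(0.1, 100.0),
    )
    def test_photic_fraction_monotone_and_capped(self, kd, kd2, depth, depth2):
        f = op.photic_fraction(kd, depth)
        assert 0.0 < f <= 100.0
        if kd2 >= kd:
            assert op.photic_fraction(kd2, depth) <= f
        if depth2 >= depth:
            assert op.photic_fraction(kd, depth2) <= f

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            op.penetration_depth_1pct(0.0)
        with pytest.raises(ValueError):
            op.photic_fraction(0.5, -1.0)


class TestColorRatios:
    def test_neutral_water_has_unit_ratios(self):
        a = op.AttenuationResult("blue", 0.8, 1.0, 10)
        b = op.AttenuationResult("green", 0.8, 1.0, 10)
        c = op.AttenuationResult("red", 0.8, 1.0, 10)
        r = op.color_ratio(a, b, c)
        assert r.blue_red == pytest.approx(1.0)
        assert r.green_red == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        a = op.AttenuationResult("blue", 0.92, 1.0, 10)
        b = op.AttenuationResult("green", 0.92, 1.0, 10)
        c = op.AttenuationResult("red", 0.46, 1.0, 10)
        assert op.color_ratio(a, b, c).blue_red == pytest.approx(0.5)

    def test_invalid_constituent_propagates(self):
        a = op.AttenuationResult("blue", -0.1, 0.5, 10, valid=False)
        b = op.AttenuationResult("green", 0.9, 1.0, 10)
        c = op.AttenuationResult("red", 0.5, 1.0, 10)
        r = op.color_ratio(a, b, c)
        assert not r.valid
        assert np.isnan(r.blue_red)

    def test_blue_red_strictly_decreasing_in_cdom(self):
        """CDOM absorbs blue preferentially, so adding CDOM with everything
        else fixed shifts the underwater color toward red."""
        cfg = syn.RiverConfig()
        ratios = []
        for acdom in [1.0, 5.0, 10.0, 20.0, 40.0]:
            import pandas as pd

            conc = pd.DataFrame(
                {"station": ["s"], "acdom340": [acdom], "tripton": [1.0], "srp": [10.0]}
            )
            kd = syn.band_kd(conc, cfg)
            ratios.append(float(kd["kd_red"].iloc[0] / kd["kd_blue"].iloc[0]))
        assert np.all(np.diff(ratios) < 0)


class TestAcdom:
    def test_zero_absorbance_gives_zero(self):
        assert op.acdom_from_absorbance(0.0, 0.0) == 0.0

    def test_direct_arithmetic(self):
        assert op.acdom_from_absorbance(0.1, 0.0, 0.01) == pytest.approx(23.03)

    def test_baseline_correction_applied(self):
        assert op.acdom_from_absorbance(0.12, 0.02, 0.01) == pytest.approx(23.03)

    def test_bad_path_length_rejected(self):
        with pytest.raises(ValueError):
            op.acdom_from_absorbance(0.1, 0.0, 0.0)


def test_roundtrip_generator_to_fit_recovers_kd_all_bands(small_river):
    """Zero-noise profiles invert exactly for every color band and station."""
    import dataclasses

    cfg = dataclasses.replace(small_river.config, profile_noise_sd=0.0)
    river = syn.simulate_river(cfg)
    kd_true = river.truth.kd.set_index("station")
    for p in river.profiles[:4]:
        for band in ("blue", "green", "red"):
            res = op.fit_kd(p, op.DEFAULT_BANDS[band])
            assert res.kd == pytest.approx(
                kd_true.loc[p.station, f"kd_{band}"], abs=1e-10
            )
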