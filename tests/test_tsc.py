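import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly

import nitrauv as nv
from nitrauv.tsc import TSCError

from conftest import ZERO_SOLUTES, make_table, pure_nitrate_overrides


class TestNormalizeSalinity:
    @pytest.mark.parametrize(
        "a, s, expected",
        [(0.2, 35.0, 0.2), (0.2, 17.5, 0.4), (0.3, 30.0, 0.35)],
    )
    def test_values(self, a, s, expected):
        assert nv.normalize_salinity(np.array([a]), s)[0] == pytest.approx(
            expected, rel=1e-12
        )

    def test_identity_at_standard_and_idempotence(self):
        a = np.array([0.1, 0.5])
        np.testing.assert_array_equal(nv.normalize_salinity(a, 35.0), a)
        once = nv.normalize_salinity(a, 31.0)
        np.testing.assert_allclose(nv.normalize_salinity(once, 35.0), once)

    def test_nonpositive_salinity_rejected(self):
        with pytest.raises(TSCError):
            nv.normalize_salinity(np.array([0.1]), 0.0)


def planted_surface_table(coeffs, wl, temps):
    """Absorbance generated exactly from a polynomial in normalized (W, T)."""
    Wg, Tg = np.meshgrid(wl, temps)
    wn = (Wg - Wg.mean()) / Wg.std()
    tn = (Tg - Tg.mean()) / Tg.std()
    A = npoly.polyval2d(wn, tn, coeffs)
    return make_table(wl, A, temps, np.full(len(temps), 35.0),
                      conc=np.zeros(len(temps)))


class TestLnsSurface:
    wl = np.linspace(208.0, 260.0, 27)
    temps = np.arange(4.0, 26.0)

    def test_planted_polynomial_recovered(self):
        rng = np.random.default_rng(5)
        coeffs = rng.standard_normal((4, 3)) * 0.1
        table = planted_surface_table(coeffs, self.wl, self.temps)
        model = nv.fit_lns_surface(table, degrees=(3, 2))
        np.testing.assert_allclose(model.coeffs, coeffs, atol=1e-8)
        assert model.r2 == pytest.approx(1.0, abs=1e-10)
        assert model.sse == pytest.approx(0.0, abs=1e-10)

    def test_constant_surface(self):
        table = make_table(self.wl, np.full((22, 27), 0.5), self.temps,
                           np.full(22, 35.0))
        model = nv.fit_lns_surface(table, degrees=(3, 2))
        assert model.coeffs[0, 0] == pytest.approx(0.5, abs=1e-10)
        assert np.abs(model.coeffs).sum() == pytest.approx(0.5, abs=1e-10)

    def test_predict_reproduces_calibration_points(self):
        rng = np.random.default_rng(6)
        coeffs = rng.standard_normal((4, 3)) * 0.1
        table = planted_surface_table(coeffs, self.wl, self.temps)
        model = nv.fit_lns_surface(table, degrees=(3, 2))
        pred = nv.predict_lns(model, *np.meshgrid(self.wl, self.temps))
        np.testing.assert_allclose(pred, table.absorbance, atol=1e-9)

    def test_predict_hand_evaluated_cubic(self):
        model = nv.LNSModel(
            w_mean=220.0, w_std=10.0, t_mean=15.0, t_std=5.0,
            degrees=(3, 0),
            coeffs=np.array([[1.0], [2.0], [-0.5], [0.25]]),
        )
        # W=230, T arbitrary: wn=1 -> 1 + 2 - 0.5 + 0.25
        assert nv.predict_lns(model, 230.0, 15.0) == pytest.approx(2.75, abs=1e-12)

    def test_p00_only_model_is_constant(self):
        model = nv.LNSModel(220.0, 10.0, 15.0, 5.0, (0, 0),
                            np.array([[0.42]]))
        out = nv.predict_lns(model, np.array([208.0, 240.0]),
                             np.array([4.0, 25.0]))
        np.testing.assert_allclose(out, 0.42)

    def test_warns_outside_span(self):
        table = planted_surface_table(np.array([[0.5]]), self.wl, self.temps)
        model = nv.fit_lns_surface(table, degrees=(0, 0))
        with pytest.warns(UserWarning, match="outside"):
            nv.predict_lns(model, 300.0, 10.0)

    def test_too_few_points_rejected(self):
        table = make_table(self.wl[:2], np.zeros((2, 2)), [4.0, 5.0],
                           [35.0, 35.0])
        with pytest.raises(TSCError):
            nv.fit_lns_surface(table, degrees=(3, 2))


class TestElementwiseSteps:
    def test_molar_absorptivity(self):
        np.testing.assert_allclose(
            nv.molar_absorptivity(np.array([0.02]), np.array([0.4]),
                                  np.array([0.2])),
            [0.04],
        )
        e = np.array([0.01, 0.02])
        np.testing.assert_array_equal(nv.molar_absorptivity(e, e * 7, e * 7), e)
        with pytest.raises(TSCError):
            nv.molar_absorptivity(e, e, np.zeros(2))

    def test_molar_absorptivity_matches_loop(self):
        rng = np.random.default_rng(2)
        E, Am, Ap = rng.random((3, 4, 6)) + 0.1
        out = nv.molar_absorptivity(E, Am, Ap)
        for i in range(4):
            for j in range(6):
                assert out[i, j] == pytest.approx(
                    E[i, j] * Am[i, j] / Ap[i, j], rel=1e-12
                )

    def test_sea_salt_absorbance(self):
        np.testing.assert_allclose(
            nv.sea_salt_absorbance(np.array([0.01]), 35.0), [0.35]
        )
        np.testing.assert_array_equal(
            nv.sea_salt_absorbance(np.array([0.01, 0.02]), 0.0), [0.0, 0.0]
        )
        with pytest.raises(TSCError):
            nv.sea_salt_absorbance(np.array([0.01]), -1.0)

    def test_remove_sea_salt(self):
        a = np.array([0.5, 0.6])
        np.testing.assert_array_equal(nv.remove_sea_salt(a, a), [0.0, 0.0])
        with pytest.raises(TSCError):
            nv.remove_sea_salt(a, np.array([0.1]))


class TestRemoveCdom:
    def test_pure_line_removed_everywhere(self, grid):
        a = 0.03 - 1e-4 * grid
        wl_out, corrected, (e, f) = nv.remove_cdom(grid, a)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-10)
        assert e == pytest.approx(0.03, abs=1e-8)
        assert f == pytest.approx(-1e-4, abs=1e-10)

    def test_nitrate_band_recovered(self, lib, grid):
        band = nv.forward_absorbance(
            lib, pure_nitrate_overrides(50e-6), grid=grid
        ).values
        line = 0.02 - 5e-5 * grid
        wl_out, corrected, _ = nv.remove_cdom(grid, band + line)
        mask = (grid >= 208.0) & (grid <= 240.0)
        np.testing.assert_allclose(corrected, band[mask], atol=1e-10)

    def test_too_few_fit_points(self):
        wl = np.array([210.0, 215.0, 245.0])
        with pytest.raises(TSCError):
            nv.remove_cdom(wl, np.zeros(3))


class TestApplyTsc:
    def zero_nitrate_table(self, lib, grid, temps, salinities):
        A = np.array([
            nv.forward_absorbance(lib, ZERO_SOLUTES, T=t, S=s, grid=grid).values
            for t, s in zip(temps, salinities)
        ])
        return make_table(grid, A, temps, salinities,
                          conc=np.zeros(len(temps)))

    def test_zero_nitrate_fully_corrected(self, lib, grid, tsc_model):
        rng = np.random.default_rng(1)
        temps = rng.uniform(4.0, 25.0, 12)
        sals = rng.uniform(30.0, 35.0, 12)
        table = self.zero_nitrate_table(lib, grid, temps, sals)
        out = nv.apply_tsc(tsc_model, table)
        assert np.abs(out.absorbance).max() < 1e-8

    def test_nitrate_spectrum_invariant_under_temperature(self, lib, grid,
                                                          tsc_model):
        temps = np.array([4.0, 9.5, 14.0, 20.0, 25.0])
        A = np.array([
            nv.forward_absorbance(
                lib, {**ZERO_SOLUTES, "sodium nitrate": 60e-6},
                T=t, S=32.0, grid=grid,
            ).values
            for t in temps
        ])
        table = make_table(grid, A, temps, np.full(5, 32.0),
                           conc=np.full(5, 60.0))
        out = nv.apply_tsc(tsc_model, table)
        spread = np.abs(out.absorbance - out.absorbance[0]).max()
        assert spread < 1e-8
        # and the corrected spectrum is the pure nitrate band
        pure = nv.forward_absorbance(lib, pure_nitrate_overrides(60e-6),
                                     grid=grid).values
        mask = (grid >= 208.0) & (grid <= 240.0)
        np.testing.assert_allclose(out.absorbance[0], pure[mask], atol=1e-8)

    def test_corrected_absorbance_uncorrelated_with_temperature(
            self, lib, grid, tsc_model):
        temps = np.linspace(4.0, 25.0, 15)
        table = self.zero_nitrate_table(lib, grid, temps, np.full(15, 34.0))
        out = nv.apply_tsc(tsc_model, table)
        col = np.argmin(np.abs(out.wavelengths - 210.0))
        a210 = out.absorbance[:, col]
        # residual variation is numerically zero -> no temperature trend
        assert np.ptp(a210) < 1e-10

    def test_window_restriction(self, lib, grid, tsc_model):
        table = nv.generate_samples(lib, 2, noise=False, seed=0, grid=grid)
        out = nv.apply_tsc(tsc_model, table)
        assert out.wavelengths[0] >= 208.0
        assert out.wavelengths[-1] <= 240.0
        assert out.n_wavelengths == 81

    def test_off_grid_table_rejected(self, lib, tsc_model):
        other = nv.default_grid(200.0, 280.0, 0.5)
        table = nv.generate_samples(lib, 2, noise=False, seed=0, grid=other)
        with pytest.raises(TSCError):
            nv.apply_tsc(tsc_model, table)
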