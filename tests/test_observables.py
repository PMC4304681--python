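import numpy as np
import pytest

from gmma.equilibria import Component, InteractionModel, Species, solve_free_concentrations
from gmma.observables import (
    ItcProtocol,
    SprCalibration,
    anisotropy_isotherm,
    effective_totals,
    fit_spr_calibration,
    generic_signal_isotherm,
    itc_heats,
    spr_competition_isotherm,
    spr_steady_isotherm,
    sw_isotherm,
)


class TestEffectiveTotals:
    def test_identity(self):
        out = effective_totals({"A": 1e-5}, {})
        assert out["A"] == pytest.approx(1e-5)

    def test_concentration_error_and_incompetent_fraction(self):
        out = effective_totals(
            {"A": 1e-5}, {"gamma.A": 0.9, "incompetent.A": 0.1}
        )
        assert out["A"] == pytest.approx(8.1e-6, rel=1e-12)

    def test_fully_incompetent(self):
        out = effective_totals({"A": 1e-5}, {"incompetent.A": 1.0})
        assert out["A"] == 0.0

    @pytest.mark.parametrize(
        "loc", [{"gamma.A": -0.5}, {"incompetent.A": 1.5}, {"incompetent.A": -0.1}]
    )
    def test_invalid_locals(self, loc):
        with pytest.raises(ValueError):
            effective_totals({"A": 1e-5}, loc)


def _itc_model(dh=-10.0, log10beta=9.0):
    return InteractionModel(
        components=[Component("A"), Component("B")],
        species=[Species("AB", {"A": 1, "B": 1}, log10beta=log10beta, dH=dh)],
    )


def _protocol(a0=1e-5, syr_b=2e-4, n_inj=20, v_inj=2e-6, v0=200e-6):
    return ItcProtocol(
        cell_volume=v0,
        syringe_concentrations={"A": 0.0, "B": syr_b},
        initial_cell_concentrations={"A": a0, "B": 0.0},
        injection_volumes=[v_inj] * n_inj,
    )


class TestItcHeats:
    def test_athermal_model_gives_zero_heats(self):
        q = itc_heats(_itc_model(dh=0.0), _protocol(), {})
        assert np.allclose(q, 0.0)

    def test_total_heat_on_saturation(self):
        """High-c titration to past 2:1 excess liberates V0*dH*A_tot."""
        v0, a0, dh = 200e-6, 1e-5, -10.0
        proto = _protocol(a0=a0, syr_b=3e-4, n_inj=20, v_inj=2e-6, v0=v0)
        q_norm = itc_heats(_itc_model(dh=dh, log10beta=9.0), proto, {})
        moles = np.asarray(proto.injection_volumes) * 3e-4
        total_raw = float(np.sum(q_norm * moles))
        assert total_raw == pytest.approx(v0 * dh * a0, rel=0.02)

    def test_displacement_titration_matches_brute_force(self):
        """Three-component competition: a stronger binder C displaces B."""
        model = InteractionModel(
            components=[Component("A"), Component("B"), Component("C")],
            species=[
                Species("AB", {"A": 1, "B": 1}, log10beta=6.0, dH=-5.0),
                Species("AC", {"A": 1, "C": 1}, log10beta=8.5, dH=-12.0),
            ],
        )
        v0 = 200e-6
        proto = ItcProtocol(
            cell_volume=v0,
            syringe_concentrations={"A": 0.0, "B": 0.0, "C": 3e-4},
            initial_cell_concentrations={"A": 1e-5, "B": 2e-5, "C": 0.0},
            injection_volumes=[2e-6] * 15,
        )
        q = itc_heats(model, proto, {})

        # independent enthalpy bookkeeping, one solve at a time
        cell = np.array([1e-5, 2e-5, 0.0])
        syr = np.array([0.0, 0.0, 3e-4])

        def enthalpy(totals):
            stt = solve_free_concentrations(model, dict(zip("ABC", totals)))
            return v0 * (
                -5.0 * stt.species_conc["AB"] - 12.0 * stt.species_conc["AC"]
            )

        h_prev = enthalpy(cell)
        expect = []
        for v in proto.injection_volumes:
            f = v / v0
            cell = cell * (1 - f) + syr * f
            h = enthalpy(cell)
            expect.append((h - h_prev + f * (h + h_prev) / 2.0) / (v * 3e-4))
            h_prev = h
        assert np.allclose(q, expect, rtol=1e-6)

    def test_telescoping_identity(self):
        """Raw heats sum exactly to H(final)-H(initial) plus the accumulated
        displacement corrections."""
        model = _itc_model()
        proto = _protocol()
        q_norm = itc_heats(model, proto, {})
        vols = np.asarray(proto.injection_volumes)
        moles = vols * proto.syringe_concentrations["B"]
        q_raw = q_norm * moles

        v0 = proto.cell_volume
        cell = np.array([1e-5, 0.0])
        syr = np.array([0.0, 2e-4])
        hs = []

        def enthalpy(totals):
            stt = solve_free_concentrations(model, {"A": totals[0], "B": totals[1]})
            return v0 * -10.0 * stt.species_conc["AB"]

        hs.append(enthalpy(cell))
        for v in vols:
            f = v / v0
            cell = cell * (1 - f) + syr * f
            hs.append(enthalpy(cell))
        hs = np.array(hs)
        corrections = (vols / v0) * (hs[1:] + hs[:-1]) / 2.0
        assert np.sum(q_raw) == pytest.approx(
            hs[-1] - hs[0] + np.sum(corrections), rel=1e-12
        )

    def test_heat_of_dilution_offset(self):
        q0 = itc_heats(_itc_model(dh=0.0), _protocol(), {})
        q1 = itc_heats(_itc_model(dh=0.0), _protocol(), {"q_dil": -0.2})
        assert np.allclose(q1 - q0, -0.2)


class TestSpr:
    def test_half_saturation(self):
        m = _itc_model()
        loc = {"Rmax": 100.0, "Kd_surf": 1e-6, "baseline": 3.0}
        # no solution partner: free analyte equals total
        r = spr_steady_isotherm(m, {"B": [1e-6], "A": [0.0]}, loc, "B")
        assert r[0] == pytest.approx(53.0)

    def test_zero_analyte_gives_baseline(self):
        m = _itc_model()
        r = spr_steady_isotherm(
            m, {"B": [0.0], "A": [0.0]}, {"Rmax": 50.0, "baseline": 1.5}, "B"
        )
        assert r[0] == pytest.approx(1.5)

    def test_solution_depletion_feeds_langmuir(self):
        """90% of the analyte bound in solution: the response reports the
        residual free concentration from the equilibrium solver."""
        m = _itc_model(log10beta=8.0)
        comps = {"A": [3e-5], "B": [1e-6]}
        loc = {"Rmax": 100.0, "Kd_surf": 1e-6, "baseline": 0.0}
        r = spr_steady_isotherm(m, comps, loc, "B")
        free_b = solve_free_concentrations(m, {"A": 3e-5, "B": 1e-6}).free["B"]
        assert free_b < 0.12e-6  # strongly depleted mixture
        assert r[0] == pytest.approx(100.0 * free_b / (1e-6 + free_b), rel=1e-12)

    def test_unknown_analyte(self):
        with pytest.raises(ValueError):
            spr_steady_isotherm(_itc_model(), {"B": [1e-6]}, {}, "X")

    def test_multivalent_surface_rejected(self):
        with pytest.raises(ValueError, match="[Mm]ultivalent"):
            spr_steady_isotherm(
                _itc_model(), {"B": [1e-6], "A": [0.0]}, {}, "B", surface_valency=2
            )


class TestSprCompetition:
    def _calibration(self):
        free = np.logspace(-8, -5, 12)
        resp = 80.0 * free / (5e-7 + free) + 2.0
        return fit_spr_calibration(free, resp)

    def test_calibration_recovers_langmuir(self):
        cal = self._calibration()
        assert cal.r_max == pytest.approx(80.0, rel=1e-6)
        assert cal.kd_surface == pytest.approx(5e-7, rel=1e-6)
        assert cal.baseline == pytest.approx(2.0, abs=1e-6)

    def test_zero_competitor_matches_direct_series(self):
        m = _itc_model()
        cal = self._calibration()
        r = spr_competition_isotherm(m, {"A": [0.0], "B": [1e-6]}, cal, "B")
        assert r[0] == pytest.approx(float(cal.response(np.array([1e-6]))[0]))

    def test_saturating_competitor_returns_baseline(self):
        m = _itc_model(log10beta=9.0)
        cal = self._calibration()
        with pytest.warns(UserWarning, match="extrapolat"):
            r = spr_competition_isotherm(m, {"A": [1e-2], "B": [1e-6]}, cal, "B")
        assert r[0] == pytest.approx(cal.baseline, abs=0.05)

    def test_missing_calibration(self):
        with pytest.raises(ValueError):
            spr_competition_isotherm(_itc_model(), {"B": [1e-6]}, None, "B")


class TestSwIsotherm:
    def test_single_species(self):
        m = InteractionModel(components=[Component("A", s=3.2)], species=[
            Species("AA", {"A": 2}, log10beta=-20.0, s=5.0)])
        sw = sw_isotherm(m, {"A": [1e-7, 1e-5]}, {"eps.A": 1.0})
        assert np.allclose(sw, 3.2)

    def test_saturating_partner_limit(self):
        m = InteractionModel(
            components=[Component("A", s=3.0), Component("B", s=4.0)],
            species=[Species("AB", {"A": 1, "B": 1}, log10beta=6.0, s=6.0)],
        )
        sw = sw_isotherm(m, {"A": [1e-7], "B": [1e-2]}, {"eps.A": 1.0, "eps.B": 0.0})
        assert sw[0] == pytest.approx(6.0, rel=1e-3)

    def test_worked_example(self, one_to_one):
        sw = sw_isotherm(
            one_to_one, {"A": [1e-6], "B": [1e-6]}, {"eps.A": 1.0, "eps.B": 1.0}
        )
        assert sw[0] == pytest.approx(4.4549, abs=1e-3)

    def test_bounded_by_species_s(self, one_to_one):
        a = np.logspace(-8, -4, 25)
        sw = sw_isotherm(
            one_to_one, {"A": a, "B": a}, {"eps.A": 1.0, "eps.B": 1.0}
        )
        assert np.all(sw >= 3.0) and np.all(sw <= 6.0)

    def test_zero_signal_is_error(self, one_to_one):
        with pytest.raises(ValueError, match="signal"):
            sw_isotherm(one_to_one, {"A": [1e-6], "B": [1e-6]},
                        {"eps.A": 0.0, "eps.B": 0.0})


class TestAnisotropy:
    def _model(self):
        return InteractionModel(
            components=[Component("P", anisotropy=0.05), Component("X")],
            species=[Species("PX", {"P": 1, "X": 1}, log10beta=12.0,
                             anisotropy=0.25)],
        )

    def test_no_partner_gives_free_anisotropy(self):
        r = anisotropy_isotherm(
            self._model(), {"P": [1e-8], "X": [0.0]}, {"r_free": 0.05}, "P"
        )
        assert r[0] == pytest.approx(0.05)

    def test_fully_bound_limit(self):
        r = anisotropy_isotherm(
            self._model(), {"P": [1e-8], "X": [1e-4]}, {"r_free": 0.05}, "P"
        )
        assert r[0] == pytest.approx(0.25, abs=1e-4)

    def test_half_bound_population_weighting(self):
        # stoichiometric binding at huge K: X_tot = P_tot/2 binds half the probe
        r = anisotropy_isotherm(
            self._model(), {"P": [1e-6], "X": [5e-7]}, {"r_free": 0.05}, "P"
        )
        assert r[0] == pytest.approx(0.15, abs=1e-3)

    def test_unknown_probe(self):
        with pytest.raises(ValueError):
            anisotropy_isotherm(self._model(), {"P": [1e-8]}, {}, "Q")


class TestGenericSignal:
    def test_zero_coefficients_give_baseline(self, one_to_one):
        s = generic_signal_isotherm(
            one_to_one, {"A": [1e-6], "B": [1e-6]}, {"baseline": 0.7}, "fl"
        )
        assert s[0] == pytest.approx(0.7)

    def test_quench_worked_example(self):
        m = InteractionModel(
            components=[Component("A", signals={"fl": 1.0}), Component("B")],
            species=[Species("AB", {"A": 1, "B": 1}, log10beta=6.0,
                             signals={"fl": 0.4})],
        )
        s = generic_signal_isotherm(
            m, {"A": [1e-6], "B": [1e-6]}, {"baseline": 0.1}, "fl"
        )
        assert s[0] == pytest.approx(0.1 + 0.618e-6 + 0.4 * 0.382e-6, rel=1e-3)

    def test_species_order_invariance(self):
        kw = dict(log10beta=7.0, dH=-8.0, s=5.0)
        m1 = InteractionModel(
            components=[Component("A", s=3.0, signals={"x": 1.0}),
                        Component("B", s=4.0, signals={"x": 2.0})],
            species=[
                Species("AB", {"A": 1, "B": 1}, **kw),
                Species("ABB", {"A": 1, "B": 2}, log10beta=12.0, s=6.0),
            ],
        )
        m2 = InteractionModel(
            components=m1.components,
            species=list(reversed(m1.species)),
        )
        comps = {"A": np.logspace(-7, -5, 5), "B": np.logspace(-7, -5, 5)}
        loc = {"eps.A": 1.0, "eps.B": 0.5}
        assert np.allclose(sw_isotherm(m1, comps, loc), sw_isotherm(m2, comps, loc))
        assert np.allclose(
            generic_signal_isotherm(m1, comps, {}, "x"),
            generic_signal_isotherm(m2, comps, {}, "x"),
        )
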