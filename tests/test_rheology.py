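"""Stress conversion, Prony/Maxwell conversions, forward model and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinmech.errors import (
    InsufficientDataError,
    InsufficientSignalError,
    InvalidGeometryError,
    InvalidInputError,
    InvalidParameterError,
)
from skinmech.rheology import (
    MaxwellBranches,
    PronyRelaxation,
    RelaxationRecord,
    branches_to_prony,
    cross_section_mm2,
    fit_relaxation,
    fit_relaxation_per_cycle,
    force_to_stress,
    mean_prony,
    prony_to_branches,
    relaxation_modulus,
    stress_response,
)
from skinmech.synthetic import simulate_relaxation_record


class TestForceToStress:
    def test_reference_geometry_cross_section(self):
        assert cross_section_mm2(1.2, 42.0) == pytest.approx(50.4)

    @pytest.mark.parametrize("force, expected", [
        (0.0, 0.0),
        (3.5, 3.5 / 50.4e-6),   # a crest-pathology peak load over S = 50.4 mm²
    ])
    def test_conversion(self, force, expected):
        assert force_to_stress(force, 1.2, 42.0) == pytest.approx(expected)

    def test_array_input(self):
        out = force_to_stress(np.array([0.0, 2.52]), 1.2, 42.0)
        assert out == pytest.approx([0.0, 2.52 / 50.4e-6])

    @pytest.mark.parametrize("e, l", [(0.0, 42.0), (1.2, -1.0)])
    def test_invalid_geometry(self, e, l):
        with pytest.raises(InvalidGeometryError):
            force_to_stress(1.0, e, l)


class TestParameterConversions:
    def test_single_branch_example(self):
        p = branches_to_prony(MaxwellBranches(2.0, ((1.0, 4.0),)))
        assert p.E0 == pytest.approx(3.0)
        assert p.terms[0] == pytest.approx((1.0 / 3.0, 4.0))

    def test_symmetric_two_branch(self):
        p = branches_to_prony(MaxwellBranches(1.0, ((1.0, 1.0), (1.0, 1.0))))
        assert [t[0] for t in p.terms] == pytest.approx([1 / 3, 1 / 3])
        assert [t[1] for t in p.terms] == pytest.approx([1.0, 1.0])

    def test_forearm_along_lines_parameters(self):
        # population means along the natural tension lines: E0 = 680.4 kPa,
        # E1 = 1382.5 kPa, eta1 = 890.3 Pa·s
        p = branches_to_prony(
            MaxwellBranches(680.4e3, ((1382.5e3, 890.3),)))
        assert p.terms[0][0] == pytest.approx(1382.5 / 2062.9, rel=1e-12)
        assert p.terms[0][1] == pytest.approx(890.3 / 1.3825e6, rel=1e-12)

    def test_inverse_recovers_branches(self):
        p = PronyRelaxation(3.0, ((1.0 / 3.0, 4.0),))
        b = prony_to_branches(p)
        assert b.E0 == pytest.approx(2.0)
        assert b.branches[0] == pytest.approx((1.0, 4.0))

    def test_purely_elastic_degenerate(self):
        b = prony_to_branches(PronyRelaxation(5.0, ()))
        assert b.E0 == pytest.approx(5.0)
        assert b.branches == ()

    def test_overweight_prony_rejected(self):
        with pytest.raises(InvalidParameterError):
            PronyRelaxation(1.0, ((0.7, 1.0), (0.4, 2.0)))

    def test_zero_branch_modulus_rejected(self):
        with pytest.raises(InvalidParameterError):
            MaxwellBranches(1.0, ((0.0, 1.0),))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        E0=st.floats(1e2, 1e7),
        p1=st.floats(0.05, 0.6),
        p2=st.floats(0.05, 0.35),
        tau1=st.floats(0.01, 5.0),
        tau2=st.floats(5.1, 100.0),
    )
    def test_round_trip_identity(self, E0, p1, p2, tau1, tau2):
        p = PronyRelaxation(E0, ((p1, tau1), (p2, tau2)))
        back = branches_to_prony(prony_to_branches(p))
        assert back.E0 == pytest.approx(p.E0, rel=1e-12)
        for (pa, ta), (pb, tb) in zip(back.terms, p.terms):
            assert pa == pytest.approx(pb, rel=1e-12)
            assert ta == pytest.approx(tb, rel=1e-12)


class TestRelaxationModulus:
    def test_standard_form_starts_at_instantaneous_modulus(self):
        p = PronyRelaxation(7.0, ((0.4, 2.0),))
        assert relaxation_modulus(p, 0.0) == pytest.approx(7.0)
        assert relaxation_modulus(p, 1e6) == pytest.approx(7.0 * 0.6)

    def test_as_printed_form_limits(self):
        p = PronyRelaxation(1.0, ((0.5, 2.0),), form="as_printed")
        assert relaxation_modulus(p, 1e9) == pytest.approx(1.0)
        assert relaxation_modulus(p, 2.0) == pytest.approx(1.0 - 0.5 * np.exp(-1))

    @pytest.mark.parametrize("form, sign", [("standard", -1.0), ("as_printed", 1.0)])
    def test_monotonicity_per_form(self, form, sign):
        p = PronyRelaxation(5e5, ((0.3, 0.7), (0.4, 9.0)), form=form)
        t = np.linspace(0.0, 60.0, 500)
        diffs = np.diff(relaxation_modulus(p, t))
        assert np.all(sign * diffs >= -1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            relaxation_modulus(PronyRelaxation(1.0, ((0.2, 1.0),)), -0.1)


class TestStressResponse:
    def test_step_strain_equals_modulus_times_strain(self):
        p = PronyRelaxation(1e5, ((0.3, 0.8), (0.3, 8.0)))
        t = np.linspace(0.0, 30.0, 400)
        sigma = stress_response(p, t, np.full_like(t, 0.2))
        expected = 0.2 * relaxation_modulus(p, t)
        np.testing.assert_allclose(sigma, expected, rtol=1e-13)

    def test_zero_strain_gives_zero_stress(self):
        p = PronyRelaxation(1e5, ((0.4, 2.0),))
        t = np.linspace(0.0, 10.0, 100)
        assert np.all(stress_response(p, t, np.zeros_like(t)) == 0.0)

    def test_ramp_matches_closed_form_convolution(self):
        # single standard-form term: sigma(t) = Einf r t + E1' r tau (1-e^(-t/tau))
        p = PronyRelaxation(1e5, ((0.4, 2.0),))
        r, tau = 0.05, 2.0
        t = np.linspace(0.0, 4.0, 2001)
        sigma = stress_response(p, t, r * t)
        closed = (0.6e5 * r * t + 0.4e5 * r * tau * (1 - np.exp(-t / tau)))
        np.testing.assert_allclose(sigma, closed, atol=1e-6 * closed.max())

    def test_ramp_then_hold_matches_dense_quadrature(self):
        from conftest import quadrature_stress

        p = PronyRelaxation(2e5, ((0.3, 0.6), (0.3, 7.0)))
        t = np.array([0.0, 1.0, 2.0, 4.0, 10.0, 20.0, 34.0])

        def strain_fn(x):
            return np.minimum(np.asarray(x, dtype=float) * 0.05, 0.2)

        grid = np.linspace(0.0, 34.0, 3401)
        dense = quadrature_stress(p, t, strain_fn, n_fine=50_001)
        ours = stress_response(p, grid, strain_fn(grid))
        idx = np.searchsorted(grid, t)
        np.testing.assert_allclose(ours[idx], dense, rtol=2e-4)

    def test_quadrature_error_is_second_order(self):
        p = PronyRelaxation(1e5, ((0.4, 2.0),))
        r, tau = 0.05, 2.0

        def err(n):
            t = np.linspace(0.0, 4.0, n)
            closed = 0.6e5 * r * t + 0.4e5 * r * tau * (1 - np.exp(-t / tau))
            return np.max(np.abs(stress_response(p, t, r * t) - closed))

        ratio = err(2001) / err(4001)
        assert 3.3 < ratio < 4.7

    def test_nonuniform_grid_matches_uniform_path(self):
        p = PronyRelaxation(1e5, ((0.4, 2.0),))
        t = np.linspace(0.0, 4.0, 1001)
        t_jig = np.unique(np.concatenate([t, [0.0005, 1.00017, 3.1413]]))
        sig = stress_response(p, t_jig, 0.05 * t_jig)
        closed = (0.6e5 * 0.05 * t_jig
                  + 0.4e5 * 0.05 * 2.0 * (1 - np.exp(-t_jig / 2.0)))
        np.testing.assert_allclose(sig, closed, atol=1e-5 * closed.max())

    def test_unsorted_grid_rejected(self):
        p = PronyRelaxation(1e5, ((0.4, 2.0),))
        with pytest.raises(InvalidInputError):
            stress_response(p, np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestFitRelaxation:
    @pytest.mark.parametrize("n_terms", [1, 2])
    def test_noiseless_recovery_within_one_percent(
            self, n_terms, one_branch_model, two_branch_model,
            single_cycle_protocol):
        model = one_branch_model if n_terms == 1 else two_branch_model
        truth = branches_to_prony(model)
        rec = simulate_relaxation_record(model, single_cycle_protocol,
                                         noise_frac=0.0)
        fit = fit_relaxation(rec, n_terms=n_terms)
        assert fit.converged
        assert fit.params.E0 == pytest.approx(truth.E0, rel=0.01)
        for (pf, tf), (pt, tt) in zip(fit.params.terms, truth.terms):
            assert pf == pytest.approx(pt, rel=0.01)
            assert tf == pytest.approx(tt, rel=0.01)

    def test_full_cycle_window_also_recovers(self, one_branch_model,
                                             single_cycle_protocol):
        truth = branches_to_prony(one_branch_model)
        rec = simulate_relaxation_record(one_branch_model,
                                         single_cycle_protocol, noise_frac=0.0)
        fit = fit_relaxation(rec, fit_window="full_cycle", n_terms=1)
        assert fit.params.E0 == pytest.approx(truth.E0, rel=0.01)

    def test_multi_cycle_fits_agree_across_cycles(self, one_branch_model):
        truth = branches_to_prony(one_branch_model)
        rec = simulate_relaxation_record(one_branch_model, noise_frac=0.0)
        fits = fit_relaxation_per_cycle(rec, n_terms=1)
        assert len(fits) == 3
        for fit in fits:
            assert fit.params.E0 == pytest.approx(truth.E0, rel=0.01)
        avg = mean_prony(fits)
        assert avg.terms[0][1] == pytest.approx(truth.terms[0][1], rel=0.01)

    def test_zero_record_rejected(self, single_cycle_protocol):
        rec = simulate_relaxation_record(
            MaxwellBranches(1e5, ((1e5, 1e5),)), single_cycle_protocol,
            noise_frac=0.0)
        dead = RelaxationRecord(rec.t, np.zeros_like(rec.y), rec.phase,
                                rec.cycle, rec.strain_history)
        with pytest.raises(InsufficientSignalError):
            fit_relaxation(dead, n_terms=1)

    def test_too_few_samples_rejected(self):
        t = np.arange(6) * 0.5
        rec = RelaxationRecord(
            t=t, y=np.array([0.0, 1.0, 2.0, 1.9, 1.8, 1.7]),
            phase=np.array(["ramp", "ramp", "ramp", "hold", "hold", "hold"]),
            cycle=np.ones(6, dtype=int),
            strain_history=np.array([0.0, 0.1, 0.2, 0.2, 0.2, 0.2]))
        with pytest.raises(InsufficientDataError):
            fit_relaxation(rec, n_terms=2)

    def test_force_units_rejected(self, one_branch_model, single_cycle_protocol):
        rec = simulate_relaxation_record(one_branch_model,
                                         single_cycle_protocol, noise_frac=0.0)
        forced = RelaxationRecord(rec.t, rec.y * 50.4e-6, rec.phase, rec.cycle,
                                  rec.strain_history, units="N")
        with pytest.raises(InvalidInputError):
            fit_relaxation(forced, n_terms=1)
        back = forced.to_stress(1.2, 42.0)
        fit = fit_relaxation(back, n_terms=1)
        assert fit.converged


class TestRecordInvariants:
    def test_decreasing_time_rejected(self):
        with pytest.raises(InvalidInputError):
            RelaxationRecord(
                t=np.array([0.0, 1.0, 0.5]), y=np.zeros(3),
                phase=np.array(["ramp", "hold", "hold"]),
                cycle=np.ones(3, int), strain_history=np.zeros(3))

    def test_strain_decreasing_in_ramp_rejected(self):
        with pytest.raises(InvalidInputError):
            RelaxationRecord(
                t=np.arange(4.0), y=np.zeros(4),
                phase=np.array(["ramp", "ramp", "hold", "hold"]),
                cycle=np.ones(4, int),
                strain_history=np.array([0.0, -0.1, 0.2, 0.2]))
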