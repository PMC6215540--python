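"""Generator contracts: conservation, limiting behaviour, determinism."""

import numpy as np
import pytest

from flavokin.fitting_engine import fit_nls, select_exponential_phases
from flavokin.kinetic_models import (BindingIsothermParams,
                                     HyperbolicReductionParams,
                                     MichaelisParams, PHBellParams,
                                     hyperbolic_kobs)
from flavokin.steady_state import fit_michaelis_dataset
from flavokin.synthetic_data import (
    MechanismParams,
    NoiseSpec,
    generate_massey_series,
    generate_ph_dataset,
    generate_reduction_trace,
    generate_titration,
    generate_velocity_dataset,
    simulate_cycle,
)


class TestCycleSimulator:
    def test_mass_conservation(self):
        p = MechanismParams()
        times = np.linspace(0, 10, 301)
        res = simulate_cycle(p, {"E_ox": 1.0, "NADPH": 100.0, "O2": 130.0,
                                 "ketone": 200.0}, times)
        E0, N0 = 1.0, 100.0
        assert np.max(np.abs(res.enzyme_total() - E0)) < 1e-8 * E0
        assert np.max(np.abs(res.nicotinamide_total() - N0)) < 1e-8 * N0

    def test_anaerobic_limit_single_exponential(self):
        """With O2 = 0 the reduced state is absorbing: the 443 nm trace is
        a single exponential at the hyperbolic rate for that [NADPH]."""
        p = MechanismParams()  # kred=59, Kd=121
        trace = generate_reduction_trace(5.0, 500.0, p)
        fr = fit_nls("exp1", trace.t, trace.A)
        expected = hyperbolic_kobs(500.0, HyperbolicReductionParams(
            kred=p.k_red, Kd_NADPH=p.Kd_NADPH))
        assert fr.params["k1"] == pytest.approx(expected, rel=0.05)

    def test_pseudo_first_order_emergence(self):
        """At NADPH0/E0 = 20 and O2 = 0 the trace deviates from the best
        single exponential by < 0.1% RMS of its amplitude."""
        trace = generate_reduction_trace(10.0, 200.0, MechanismParams())
        fr = fit_nls("exp1", trace.t, trace.A)
        rms = np.sqrt(fr.rss / fr.n_obs)
        assert rms < 1e-3 * abs(fr.params["a1"])

    def test_uncoupling_dominates_reoxidation_without_substrate(self):
        """Starting from reduced enzyme + NADP+, aerobic recovery at
        440 nm is governed by the peroxyflavin decay (0.47 s⁻¹)."""
        p = MechanismParams()  # k_uncouple=0.47
        times = np.linspace(0, 20, 600)
        res = simulate_cycle(p, {"E_red": 20.0, "NADP": 500.0, "O2": 130.0},
                             times)
        sel = select_exponential_phases(times, res.absorbance(440.0))
        fit = sel.fits[sel.chosen]
        amps = {fit.params[a]: fit.params[k]
                for a, k in (("a1", "k1"), ("a2", "k2")) if a in fit.params}
        dominant_rate = amps[min(amps)]  # most negative amplitude = rise
        assert dominant_rate == pytest.approx(0.47, rel=0.1)

    def test_steady_state_self_consistency(self):
        """Without the uncoupling branch, simulated NADPH consumption
        follows Michaelis-Menten kinetics in the ketone, and the fitted
        kcat matches the simulator's saturating turnover; with the default
        uncoupling the saturating turnover stays near the reference
        butanone kcat."""
        from dataclasses import replace

        def velocities(p, grid):
            E0, out = 0.5, []
            for ket in grid:
                times = np.linspace(0, 4, 201)
                res = simulate_cycle(p, {"E_ox": E0, "NADPH": 100.0,
                                         "O2": 130.0, "ketone": ket}, times)
                m = times >= 2.0  # post-transient window
                slope = -np.polyfit(times[m], res.species("NADPH")[m], 1)[0]
                out.append((ket, slope / E0))
            return (np.array([r[0] for r in out]),
                    np.array([r[1] for r in out]))

        grid = [5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 1000.0, 3000.0]
        S, v = velocities(replace(MechanismParams(), k_uncouple=0.0), grid)
        fr = fit_nls("michaelis", S, v)
        assert fr.r2 > 0.999         # consumption is hyperbolic in ketone
        assert fr.params["kcat"] == pytest.approx(v[-1], rel=0.05)
        # default parameterization reproduces the reference turnover at
        # the saturating assay condition (200 µM butanone)
        _, v_def = velocities(MechanismParams(), [200.0])
        assert v_def[0] == pytest.approx(2.1, rel=0.10)

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_cycle(MechanismParams(), {"E_ox": -1.0},
                           np.linspace(0, 1, 10))

    def test_kd_consistency(self):
        p = MechanismParams.with_Kd(121.0)
        assert p.Kd_NADPH == pytest.approx(121.0, rel=1e-9)


class TestMasseyGenerator:
    def test_midpoint_half_reduced(self):
        """When the solution potential equals the enzyme midpoint the
        enzyme is exactly half reduced."""
        ms = generate_massey_series(E0_enzyme_mV=-166.0,
                                    schedule=np.linspace(1, 79, 400))
        i = np.argmin(np.abs(ms.potential_V - (-0.166)))
        assert ms.f_enzyme[i] == pytest.approx(0.5, abs=2e-3)

    def test_points_exactly_on_nernst_line(self):
        """(log E ratio, log D ratio) pairs fall on the two-couple line
        with slope ne/nd and the analytic intercept."""
        ms = generate_massey_series(E0_enzyme_mV=-166.0, ne=2,
                                    E0_dye_mV=-116.0, nd=2)
        ok = (ms.f_enzyme > 1e-6) & (ms.f_enzyme < 1 - 1e-6) & \
             (ms.f_dye > 1e-6) & (ms.f_dye < 1 - 1e-6)
        x = np.log10(ms.f_dye[ok] / (1 - ms.f_dye[ok]))
        y = np.log10(ms.f_enzyme[ok] / (1 - ms.f_enzyme[ok]))
        intercept = 2 * (-0.166 + 0.116) / 0.0592
        assert np.max(np.abs(y - (x + intercept))) < 1e-10

    def test_log_ratio_monotone_in_equivalents(self):
        ms = generate_massey_series(schedule=np.linspace(1, 79, 100))
        logratio = np.log10(ms.f_enzyme / (1 - ms.f_enzyme))
        assert np.all(np.diff(logratio) > 0)

    def test_schedule_outside_range_rejected(self):
        with pytest.raises(ValueError):
            generate_massey_series(schedule=np.array([10.0, 100.0]))


class TestDirectGenerators:
    def test_velocity_dataset_round_trip(self):
        truth = MichaelisParams(kcat=2.1, Km=0.34)
        records = generate_velocity_dataset(
            truth, np.array([0.05, 0.1, 0.34, 0.7, 1.5, 5.0]))
        p, _, _ = fit_michaelis_dataset(records)
        assert p.kcat == pytest.approx(2.1, rel=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_velocity_dataset(MichaelisParams(2.1, 0.34),
                                      np.array([]))

    def test_titration_baseline_zero(self):
        truth = BindingIsothermParams(0.1, 50.0, 21.1)
        series = generate_titration(truth, np.arange(0.0, 201.0, 10.0),
                                    NoiseSpec(sigma=0.002, seed=3))
        assert series.dA[0] == 0.0

    def test_seeded_determinism_and_seed_sensitivity(self):
        truth = PHBellParams(Y_H=2.1, pKa_low=5.6, pKa_high=9.2)
        grid = np.arange(5.5, 9.01, 0.25)
        _, a = generate_ph_dataset(truth, grid, NoiseSpec(0.05, seed=42))
        _, b = generate_ph_dataset(truth, grid, NoiseSpec(0.05, seed=42))
        _, c = generate_ph_dataset(truth, grid, NoiseSpec(0.05, seed=43))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_reduction_trace_determinism(self):
        a = generate_reduction_trace(10.0, 100.0, noise=NoiseSpec(0.001, 1))
        b = generate_reduction_trace(10.0, 100.0, noise=NoiseSpec(0.001, 1))
        assert np.array_equal(a.A, b.A)

    def test_no_coenzyme_gives_flat_oxidized_trace(self):
        trace = generate_reduction_trace(10.0, 0.0)
        assert np.ptp(trace.A) < 1e-12
        assert trace.A[0] == pytest.approx(10.0 * 1e-6 * 12200.0)
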