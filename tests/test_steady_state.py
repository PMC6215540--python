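"""Steady-state pipeline: velocities, Michaelis/inhibition fits, pH,
thermostability."""

import numpy as np
import pytest

from flavokin.fitting_engine import FitError
from flavokin.kinetic_models import MichaelisParams, PHBellParams
from flavokin.steady_state import (
    VelocityRecord,
    fit_competitive_inhibition,
    fit_michaelis_dataset,
    fit_ph_profile,
    fold_change,
    thermostability_summary,
    trace_to_velocity,
)
from flavokin.synthetic_data import (NoiseSpec, generate_ph_dataset,
                                     generate_progress_curve,
                                     generate_velocity_dataset)


class TestTraceToVelocity:
    def test_slope_conversion(self):
        """-0.00622 AU/s at Δε340 = 6220 M⁻¹cm⁻¹ is 1.0 µM NADPH/s."""
        t = np.linspace(0, 20, 101)
        A = 0.8 - 0.00622 * t
        rec = trace_to_velocity(t, A, E0=0.5)
        assert rec.v == pytest.approx(1.0 / 0.5, rel=1e-9)  # turnover s^-1

    def test_flat_trace_zero_velocity(self):
        t = np.linspace(0, 20, 101)
        rec = trace_to_velocity(t, np.full_like(t, 0.8), E0=0.5)
        assert rec.v == pytest.approx(0.0, abs=1e-12)

    def test_short_window_rejected(self):
        with pytest.raises(FitError):
            trace_to_velocity(np.array([0, 10, 20, 30.0]),
                              np.array([0.8, 0.7, 0.6, 0.5]), E0=0.5)

    def test_unit_conversion_in_record(self):
        rec = VelocityRecord("butanone", 200.0, 0.0, 0.5, 1.0,
                             unit="uM_per_s")
        assert rec.turnover() == pytest.approx(2.0)


class TestMichaelisFit:
    @pytest.mark.parametrize("kcat, Km, grid", [
        (2.1, 0.34, [0.05, 0.1, 0.34, 0.7, 1.5, 5.0]),       # butanone-like
        (1.4, 170.0, [20, 50, 170, 400, 1000, 5000.0]),      # acetone-like
    ])
    def test_noiseless_recovery(self, kcat, Km, grid):
        records = generate_velocity_dataset(
            MichaelisParams(kcat=kcat, Km=Km), np.array(grid))
        p, fr, summary = fit_michaelis_dataset(records)
        assert p.kcat == pytest.approx(kcat, rel=1e-6)
        assert p.Km == pytest.approx(Km, rel=1e-6)
        # efficiency consistent with kcat/Km (Km µM -> M)
        assert summary.kcat_over_Km == pytest.approx(
            p.kcat / (p.Km * 1e-6), rel=1e-12)

    def test_single_concentration_rejected(self):
        records = [VelocityRecord("x", 1.0, 0.0, 0.03, 1.0)] * 6
        with pytest.raises(FitError):
            fit_michaelis_dataset(records)

    def test_saturation_warning(self):
        truth = MichaelisParams(kcat=1.4, Km=170.0)
        records = generate_velocity_dataset(truth,
                                            np.array([1, 2, 4, 8, 16.0]))
        _, fr, _ = fit_michaelis_dataset(records)
        assert "saturation_not_reached" in fr.flags


class TestCompetitiveInhibition:
    truth = MichaelisParams(kcat=2.0, Km=6.7, Ki=166.0)
    S = np.array([0.2, 0.5, 1, 2, 5, 10, 25, 50, 100.0])
    I = np.array([0.0, 250.0, 500.0, 1000.0])

    def test_noiseless_global_recovery(self):
        records = generate_velocity_dataset(self.truth, self.S, self.I)
        p, fr = fit_competitive_inhibition(records)
        assert p.kcat == pytest.approx(2.0, rel=1e-6)
        assert p.Km == pytest.approx(6.7, rel=1e-6)
        assert p.Ki == pytest.approx(166.0, rel=1e-6)

    def test_lineweaver_burk_signature(self):
        """At each inhibitor level the apparent Km equals Km(1+I/Ki)."""
        records = generate_velocity_dataset(self.truth, self.S, self.I)
        p, _ = fit_competitive_inhibition(records)
        for I_level in self.I[1:]:
            sub = [r for r in records if r.I == I_level]
            S = np.array([r.S for r in sub])
            v = np.array([r.v for r in sub])
            from flavokin.fitting_engine import fit_nls
            fr = fit_nls("michaelis", S, v)
            assert fr.params["Km"] == pytest.approx(
                p.Km * (1 + I_level / p.Ki), rel=1e-6)

    def test_uninhibited_subset_reduces_to_michaelis(self):
        records = generate_velocity_dataset(self.truth, self.S,
                                            np.array([0.0]))
        with pytest.raises(FitError):
            fit_competitive_inhibition(records)  # one I level: unidentifiable
        p, fr, _ = fit_michaelis_dataset(records)
        assert p.kcat == pytest.approx(2.0, rel=1e-6)
        assert p.Km == pytest.approx(6.7, rel=1e-6)


def test_end_to_end_trace_recovery():
    """Progress curves -> initial velocities -> Michaelis fit recovers the
    generating constants within 2% when sampling stays in the initial
    depletion regime."""
    truth = MichaelisParams(kcat=2.1, Km=0.34)
    E0 = 0.03
    records = []
    for S0 in [0.05, 0.1, 0.2, 0.34, 0.7, 1.5, 5.0]:
        # sample well inside 10% substrate depletion
        t_max = 0.02 * S0 / (E0 * truth.kcat)
        trace = generate_progress_curve(truth, S0, E0, 100.0,
                                        np.linspace(0, t_max, 60))
        rec = trace_to_velocity(trace.t, trace.A, E0=E0, S=S0,
                                substrate_id="butanone")
        records.append(rec)
    p, _, _ = fit_michaelis_dataset(records)
    assert p.kcat == pytest.approx(2.1, rel=0.02)
    assert p.Km == pytest.approx(0.34, rel=0.02)


class TestFoldChange:
    def test_reference_ratios(self):
        assert fold_change(170.0, 0.34) == pytest.approx(500.0)
        # uncoupled oxidation vs turnover: computed, not rounded to prose
        assert fold_change(2.1, 0.26) == pytest.approx(8.0769, abs=1e-3)
        assert fold_change(3.0, 3.0) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(1.0, 0.0)


class TestPhProfile:
    def test_noiseless_pka_recovery(self):
        truth = PHBellParams(Y_H=2.1, pKa_low=5.6, pKa_high=9.2)
        pH, v = generate_ph_dataset(truth, np.arange(5.5, 9.01, 0.25))
        p, fr = fit_ph_profile(pH, v)
        assert p.pKa_low == pytest.approx(5.6, rel=1e-6)
        assert p.pKa_high == pytest.approx(9.2, rel=1e-6)
        assert fr.converged

    def test_symmetric_data_peak_at_midpoint(self):
        truth = PHBellParams(Y_H=1.0, pKa_low=6.0, pKa_high=8.0)
        pH, v = generate_ph_dataset(truth, np.arange(4.0, 10.01, 0.25))
        assert pH[np.argmax(v)] == pytest.approx(7.0, abs=0.13)

    def test_canonical_ordering_from_swapped_init(self):
        truth = PHBellParams(Y_H=2.1, pKa_low=5.6, pKa_high=9.2)
        pH, v = generate_ph_dataset(truth, np.arange(5.0, 9.51, 0.25))
        p, _ = fit_ph_profile(pH, v)
        assert p.pKa_low < p.pKa_high
        assert p.pKa_low == pytest.approx(5.6, rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_ph_profile(np.array([6, 7, 8.0]), np.array([1, 2, 1.0]))


class TestThermostability:
    def test_all_equal_gives_unit_fractions(self):
        rows = thermostability_summary([5, 15, 25], [1.0, 1.0, 1.0])
        assert all(r["fraction"] == 1.0 for r in rows)
        assert not any(r["declined"] for r in rows)

    def test_decline_flag_above_25C(self):
        rows = thermostability_summary([5, 30], [1.0, 0.35])
        assert rows[1]["fraction"] == pytest.approx(0.35)
        assert rows[1]["declined"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            thermostability_summary([], [])
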