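"""Whole-body ODE system: structure, conservation, and analytic oracles."""

import dataclasses

import numpy as np
import pytest

from asipbpk import (
    CalibrationFactors,
    DoseRegimen,
    TissueSpec,
    VirtualSubject,
    build_odes,
    calibrate_to_observed,
    effective_kp,
    simulate,
)
from asipbpk.pbpk import STATE_NAMES, ConcentrationTimeSeries


def _high_flow(subject, factor=1e4):
    """Same anatomy with blood flows scaled up: the well-mixed limit."""
    return VirtualSubject(
        body_weight=subject.body_weight,
        tissues=tuple(
            TissueSpec(t.name, t.volume, t.blood_flow * factor) for t in subject.tissues
        ),
        venous_volume=subject.venous_volume,
        arterial_volume=subject.arterial_volume,
    )


class TestEffectiveKp:
    def test_printed_tissue_scaled(self, records):
        rec = dataclasses.replace(records["Baxdrostat"], kp_scaler=0.14)
        assert effective_kp(rec, "liver") == pytest.approx(4.75 * 0.14)

    def test_identity_scaler_returns_printed_kp(self, records):
        rec = dataclasses.replace(records["Dexfadrostat"], kp_scaler=1.0)
        for tissue, kp in rec.kp.items():
            assert effective_kp(rec, tissue) == pytest.approx(kp)

    def test_surrogate_tissues(self, library):
        for rec in library:
            assert effective_kp(rec, "stomach") == pytest.approx(effective_kp(rec, "gut"))
            assert effective_kp(rec, "pancreas") == pytest.approx(
                effective_kp(rec, "spleen")
            )
            mean_kp = np.mean(list(rec.kp.values()))
            assert effective_kp(rec, "rest_of_body") == pytest.approx(
                mean_kp * rec.kp_scaler
            )

    def test_unknown_tissue_rejected(self, records):
        with pytest.raises(ValueError, match="unknown tissue"):
            effective_kp(records["LCI699"], "gallbladder")


class TestSystemStructure:
    def test_zero_state_gives_zero_derivative(self, records, subject70):
        system = build_odes(records["Baxdrostat"], subject70)
        assert np.allclose(system.rhs(0.0, np.zeros(len(STATE_NAMES))), 0.0)

    def test_total_mass_is_conserved_by_construction(self, records, subject70):
        # column sums of the rate matrix vanish: whatever leaves one
        # compartment enters another (eliminated included)
        system = build_odes(records["Lorundrostat"], subject70)
        assert np.allclose(system.matrix.sum(axis=0), 0.0, atol=1e-12)

    def test_uniform_equilibrium_when_no_clearance(self, subject70, make_compound):
        # with CL = 0, Kp = 1, bpr = 1 the steady state has equal
        # concentration everywhere: the all-volumes vector is a null vector
        rec = make_compound(cl_app=1e-12, kp=1.0, bpr=1.0)
        system = build_odes(rec, subject70)
        v = np.zeros(len(STATE_NAMES))
        for i, name in enumerate(STATE_NAMES):
            if name == "venous":
                v[i] = subject70.venous_volume
            elif name == "arterial":
                v[i] = subject70.arterial_volume
            elif name not in ("depot", "eliminated"):
                v[i] = subject70.tissue(name).volume
        residual = system.matrix @ v
        assert np.allclose(residual, 0.0, atol=1e-9)

    def test_flow_imbalanced_subject_rejected_at_build(self, records, subject70):
        bad = VirtualSubject.__new__(VirtualSubject)
        object.__setattr__(bad, "body_weight", 70.0)
        object.__setattr__(
            bad,
            "tissues",
            tuple(
                TissueSpec(t.name, t.volume,
                           t.blood_flow * (2.0 if t.name == "muscle" else 1.0))
                for t in subject70.tissues
            ),
        )
        object.__setattr__(bad, "venous_volume", 3.9)
        object.__setattr__(bad, "arterial_volume", 1.3)
        with pytest.raises(ValueError, match="flow-imbalanced"):
            build_odes(records["Baxdrostat"], bad)


class TestSimulate:
    def test_zero_dose_gives_zero_series(self, records, subject70):
        ts = simulate(records["LCI699"], subject70, DoseRegimen(dose=0.0), 24.0, 0.5)
        assert np.all(ts.plasma_conc == 0.0)
        assert np.all(ts.amounts == 0.0)

    def test_mass_conserved_without_clearance(self, subject70, make_compound):
        rec = make_compound(cl_app=1e-12, kp=2.0)
        regimen = DoseRegimen(dose=5.0, n_doses=3, interval=24.0)
        ts = simulate(rec, subject70, regimen, 96.0, 0.5)
        doses_given = np.minimum(np.floor(ts.times / 24.0) + 1, 3) * 5.0
        in_body = ts.total_amount - ts.amount("eliminated")
        assert np.allclose(in_body, doses_given, rtol=1e-6)

    def test_mass_balance_with_elimination(self, records, subject70):
        regimen = DoseRegimen(dose=10.0, n_doses=4, interval=24.0)
        ts = simulate(records["Dexfadrostat"], subject70, regimen, 120.0, 0.5)
        doses_given = np.minimum(np.floor(ts.times / 24.0) + 1, 4) * 10.0
        assert np.allclose(ts.total_amount, doses_given, rtol=1e-6)

    def test_dose_linearity(self, records, subject70):
        lo = simulate(records["Baxdrostat"], subject70, DoseRegimen(dose=1.0), 48.0, 0.25)
        hi = simulate(records["Baxdrostat"], subject70, DoseRegimen(dose=10.0), 48.0, 0.25)
        mask = lo.plasma_conc > lo.plasma_conc.max() * 1e-6
        assert np.allclose(hi.plasma_conc[mask] / lo.plasma_conc[mask], 10.0, rtol=1e-3)

    def test_superposition_mad_equals_shifted_sad(self, records, subject70):
        rec = records["LCI699"]
        dt = 0.25
        sad = simulate(rec, subject70, DoseRegimen(dose=5.0), 96.0, dt)
        mad = simulate(rec, subject70, DoseRegimen(dose=5.0, n_doses=3), 96.0, dt)
        shift = int(round(24.0 / dt))
        expected = sad.plasma_conc.copy()
        for k in (1, 2):
            expected[k * shift:] += sad.plasma_conc[: sad.plasma_conc.size - k * shift]
        scale = expected.max()
        assert np.allclose(mad.plasma_conc, expected, atol=1e-3 * scale)

    def test_infusion_steady_state_css_equals_rate_over_clearance(
        self, subject70, make_compound
    ):
        # small distribution volume + high clearance => short half-life, so
        # the horizon covers many half-lives
        rec = make_compound(kp=0.1, cl_app=25.0)
        rate = 2.0  # mg/h into the venous pool
        ts = simulate(rec, subject70, DoseRegimen(dose=0.0), 60.0, 0.5,
                      infusion_rate=rate)
        css_ng_ml = rate / rec.cl_app * 1000.0
        assert ts.plasma_conc[-1] == pytest.approx(css_ng_ml, rel=1e-3)

    def test_one_tissue_collapse_matches_bateman(self, subject70, make_compound):
        # in the high-flow limit with uniform Kp = 1 and bpr = 1 the body is
        # one well-mixed volume; oral dosing then follows the Bateman equation
        rec = make_compound(kp=1.0, bpr=1.0, cl_app=12.0, gi_ka=0.8)
        fast = _high_flow(subject70)
        dose = 10.0
        ts = simulate(rec, fast, DoseRegimen(dose=dose), 72.0, 0.25)
        v = fast.total_volume
        ka, ke = rec.gi_ka, rec.cl_app / v
        t = ts.times
        analytic = (
            dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t)) * 1000.0
        )
        assert np.allclose(ts.plasma_conc, analytic, atol=1e-3 * analytic.max())

    def test_auc_monotone_in_cl_divisor(self, records, subject70):
        from asipbpk import auc

        rec = records["BI689648"]
        aucs = []
        for divisor in (1.0, 2.0, 4.7, 8.0):
            cal = dataclasses.replace(rec, cl_app=rec.cl_app / divisor)
            ts = simulate(cal, subject70, DoseRegimen(dose=5.0), 96.0, 0.5)
            aucs.append(auc(ts, 0.0, 96.0))
        assert all(b > a for a, b in zip(aucs, aucs[1:]))

    def test_t_end_must_cover_last_dose(self, records, subject70):
        with pytest.raises(ValueError, match="last dose"):
            simulate(records["Baxdrostat"], subject70,
                     DoseRegimen(dose=1.0, n_doses=5, interval=24.0), 48.0, 0.5)


class TestSeriesValidation:
    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError, match="starting at 0"):
            ConcentrationTimeSeries(
                times=np.array([1.0, 2.0]),
                plasma_conc=np.zeros(2),
                amounts=np.zeros((2, len(STATE_NAMES))),
            )

    def test_negative_amounts_beyond_tolerance_rejected(self):
        amounts = np.zeros((2, len(STATE_NAMES)))
        amounts[1, 0] = -1.0
        with pytest.raises(ValueError, match="negative compartment"):
            ConcentrationTimeSeries(
                times=np.array([0.0, 1.0]),
                plasma_conc=np.zeros(2),
                amounts=amounts,
            )

    def test_tiny_negative_amounts_are_clipped(self):
        amounts = np.zeros((2, len(STATE_NAMES)))
        amounts[1, 0] = -1e-12
        ts = ConcentrationTimeSeries(
            times=np.array([0.0, 1.0]), plasma_conc=np.zeros(2), amounts=amounts
        )
        assert ts.amounts.min() == 0.0


class TestCalibrationSearch:
    def test_self_recovery_from_grid(self, records, subject70):
        rec = records["Baxdrostat"]
        regimen = DoseRegimen(dose=2.5)
        from asipbpk import apply_calibration

        truth = apply_calibration(rec, CalibrationFactors(0.85, 4.7))
        ts = simulate(truth, subject70, regimen, 48.0, 0.5)
        observed = ts.to_frame()[["time_h", "plasma_ng_per_mL"]].rename(
            columns={"plasma_ng_per_mL": "conc_ng_per_mL"}
        )[::8]
        found = calibrate_to_observed(
            rec, subject70, regimen, observed,
            kp_factors=[0.75, 0.85, 0.95], cl_divisors=[3.7, 4.7, 5.7],
            dt_out=0.5, t_end=48.0,
        )
        assert (found.kp_factor, found.cl_divisor) == (0.85, 4.7)

    def test_single_point_grid_returned(self, records, subject70):
        rec = records["LCI699"]
        regimen = DoseRegimen(dose=1.0)
        ts = simulate(rec, subject70, regimen, 36.0, 1.0)
        observed = ts.to_frame()[["time_h", "plasma_ng_per_mL"]].rename(
            columns={"plasma_ng_per_mL": "conc_ng_per_mL"}
        )
        found = calibrate_to_observed(
            rec, subject70, regimen, observed, [0.5], [2.0], dt_out=1.0, t_end=36.0
        )
        assert (found.kp_factor, found.cl_divisor) == (0.5, 2.0)

    def test_empty_grid_and_sparse_observed_rejected(self, records, subject70):
        import pandas as pd

        rec = records["LCI699"]
        regimen = DoseRegimen(dose=1.0)
        obs = pd.DataFrame({"time_h": [1.0, 2.0, 3.0], "conc_ng_per_mL": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="non-empty"):
            calibrate_to_observed(rec, subject70, regimen, obs, [], [4.7])
        short = obs.iloc[:2]
        with pytest.raises(ValueError, match="at least 3"):
            calibrate_to_observed(rec, subject70, regimen, short, [0.85], [4.7])
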