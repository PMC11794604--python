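"""Unit and property tests for the minimal PBPK / TMDD simulator."""

import dataclasses
import math

import numpy as np
import pytest

from mtpa.batch import run_cohort_batch
from mtpa.endpoints import pk_endpoints
from mtpa.model_core import (DoseRegimen, DrugProperties, MinimalPBPKModel,
                             TargetProperties, build_model,
                             charge_adjusted_rates)


def make_model(phys, cfg, *, kd=9.0, t0=1.0, t_half=10.0, form="soluble",
               charge=0, dose=1.0, interval=14.0, **solver_extra):
    opts = dict(cfg["solver"])
    opts.update(solver_extra)
    return MinimalPBPKModel(
        DrugProperties(kd=kd, charge=charge, kon=cfg["drug_defaults"]["kon"]),
        TargetProperties(t0=t0, t_half=t_half, form=form),
        phys, DoseRegimen(dose=dose, interval_days=interval), opts)


class TestDerivedRates:
    def test_membrane_internalization_equals_degradation(self, phys):
        ps = build_model(DrugProperties(kd=1.0),
                         TargetProperties(t0=1.0, t_half=1.0,
                                          form="membrane"),
                         phys, DoseRegimen(1.0))
        assert ps.rates.kint == pytest.approx(math.log(2), rel=1e-12)
        assert ps.rates.kint == ps.rates.kdeg

    def test_soluble_internalization_equals_elimination(self, phys):
        ps = build_model(DrugProperties(kd=1.0),
                         TargetProperties(t0=1.0, t_half=5.0),
                         phys, DoseRegimen(1.0))
        assert ps.rates.kint == ps.rates.kel
        assert ps.rates.kel == pytest.approx(
            phys.cl_plasma / 24.0 / phys.v_plasma)

    def test_koff_is_kon_times_kd(self, phys):
        ps = build_model(DrugProperties(kd=9.0, kon=0.36),
                         TargetProperties(t0=1.0, t_half=5.0),
                         phys, DoseRegimen(1.0))
        assert ps.rates.koff == pytest.approx(3.24)

    def test_zero_baseline_means_zero_synthesis(self, phys):
        ps = build_model(DrugProperties(kd=1.0),
                         TargetProperties(t0=0.0, t_half=5.0),
                         phys, DoseRegimen(1.0))
        assert ps.rates.ksyn == 0.0

    def test_dose_conversion_to_nmol(self, phys):
        ps = build_model(DrugProperties(kd=1.0, mw=150000.0),
                         TargetProperties(t0=1.0, t_half=5.0),
                         phys, DoseRegimen(1.0))
        assert ps.dose_nmol == pytest.approx(1.0 * phys.bw * 1e6 / 150000.0)

    @pytest.mark.parametrize("bad", [
        dict(kd=0.0), dict(kd=-1.0), dict(mw=0.0), dict(kon=0.0)])
    def test_invalid_drug_rejected(self, bad):
        kw = dict(kd=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            DrugProperties(**kw)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            TargetProperties(t0=1.0, t_half=0.0)
        with pytest.raises(ValueError):
            TargetProperties(t0=-1.0, t_half=1.0)
        with pytest.raises(ValueError):
            TargetProperties(t0=1.0, t_half=1.0, form="membrane", sites=())


class TestChargeScaling:
    def test_identity_at_zero_charge(self, phys):
        cl, up_t, up_l = charge_adjusted_rates(phys, 0)
        assert cl == phys.cl_plasma
        assert up_t == phys.cl_up_tight
        assert up_l == phys.cl_up_leaky

    def test_monotone_in_charge(self, phys):
        cls = [charge_adjusted_rates(phys, q)[0] for q in (-5, 0, 5)]
        assert cls[0] < cls[1] < cls[2]

    def test_exponential_factor(self, phys):
        phys2 = dataclasses.replace(phys, charge_cl_coeff=0.2)
        cl, _, _ = charge_adjusted_rates(phys2, 5)
        assert cl == pytest.approx(phys.cl_plasma * math.e, rel=1e-12)

    def test_trough_exposure_nonincreasing_in_charge(self, phys, cfg):
        cmins = []
        for q in (-5, 0, 5):
            m = make_model(phys, cfg, kd=100.0, t0=1e-3, charge=q)
            traj = m.run_to_steady_state(max_intervals=30)
            cmins.append(pk_endpoints(traj).c_min)
        assert cmins[0] > cmins[1] > cmins[2]


class TestSimulate:
    def test_no_dose_keeps_target_at_baseline(self, phys, cfg):
        m = make_model(phys, cfg, t0=5.0, t_half=2.0, dose=0.0)
        traj = m.simulate(500.0)
        assert np.all(traj.drug("plasma") == 0.0)
        for site in ("plasma", "tight", "leaky"):
            rel = np.abs(traj.free_target(site) - 5.0) / 5.0
            assert rel.max() < 1e-6

    def test_drug_mass_conserved_without_elimination(self, phys, cfg):
        phys0 = dataclasses.replace(phys, cl_plasma=1e-12, cl_up_tight=0.0,
                                    cl_up_leaky=0.0)
        m = make_model(phys0, cfg, kd=1.0, t0=10.0, t_half=1e9,
                       interval=None)
        traj = m.simulate(28 * 24.0)
        amount = (phys.v_plasma * (traj.drug("plasma")
                                   + traj.complex("plasma"))
                  + phys.v_tight * (traj.drug("tight")
                                    + traj.complex("tight"))
                  + phys.v_leaky * (traj.drug("leaky")
                                    + traj.complex("leaky"))
                  + phys.v_lymph * traj.states[:, 3])
        drift = np.abs(amount - amount[0]) / amount[0]
        assert drift.max() < 1e-3

    def test_states_nonnegative(self, phys, cfg):
        m = make_model(phys, cfg, kd=0.01, t0=100.0, t_half=0.1)
        traj = m.run_to_steady_state(max_intervals=30)
        assert traj.states.min() >= 0.0

    def test_tidy_export_schema(self, phys, cfg):
        m = make_model(phys, cfg, dose=1.0, interval=None)
        df = m.simulate(48.0).to_frame("c000001", "base")
        assert list(df.columns) == ["time_h", "compartment", "species",
                                    "conc_nM", "candidate_id",
                                    "scenario_id"]
        assert set(df["species"]) == {"drug", "target", "complex"}
        assert set(df["compartment"]) == {"plasma", "tight", "leaky",
                                          "lymph"}
        assert (df["candidate_id"] == "c000001").all()

    def test_t_end_must_cover_doses(self, phys, cfg):
        m = make_model(phys, cfg)
        with pytest.raises(ValueError):
            m.simulate(100.0, n_doses=3)   # doses at 0, 336, 672 h


class TestClampedOccupancy:
    @pytest.mark.parametrize("ratio", [0.1, 1.0, 10.0])
    def test_closed_form_occupancy(self, phys, cfg, ratio):
        """With plasma concentration clamped at C and kint = 0, the target
        subsystem settles at TO = 100*C/(C+KD) (4 significant figures)."""
        kd = 10.0
        clamp = ratio * kd
        phys0 = dataclasses.replace(phys, cl_plasma=1e-30)  # kint = kel = 0
        m = make_model(phys0, cfg, kd=kd, t0=1.0, t_half=1.0,
                       clamp_plasma=clamp)
        traj = m.simulate(500.0)
        to = 100.0 * traj.complex("plasma")[-1] / (
            traj.free_target("plasma")[-1] + traj.complex("plasma")[-1])
        expected = 100.0 * clamp / (clamp + kd)
        assert to == pytest.approx(expected, rel=1e-4)


class TestSteadyState:
    def test_linear_pk_accumulates_like_analytic_ratio(self, phys, cfg):
        """Fast-clearing linear PK (no target) converges within 3 intervals
        and its trough matches the one-compartment accumulation limit."""
        phys_fast = dataclasses.replace(phys, cl_plasma=8.0,
                                        l_tight=1e-6, l_leaky=1e-6)
        m = make_model(phys_fast, cfg, kd=1e3, t0=0.0)
        traj = m.run_to_steady_state()
        assert traj.converged and traj.n_intervals <= 3
        kel = 8.0 / 24.0 / phys.v_plasma
        tau = 14 * 24.0
        c0 = m.params.dose_increment_nM
        expected = c0 * math.exp(-kel * tau) / (1 - math.exp(-kel * tau))
        assert pk_endpoints(traj).c_min == pytest.approx(expected, rel=1e-3)

    def test_zero_clearance_never_converges(self, phys, cfg):
        phys0 = dataclasses.replace(phys, cl_plasma=1e-12, cl_up_tight=0.0,
                                    cl_up_leaky=0.0)
        m = make_model(phys0, cfg, t0=0.0)
        traj = m.run_to_steady_state(max_intervals=5)
        assert not traj.converged
        assert traj.n_intervals == 5

    def test_endpoints_use_final_interval_only(self, phys, cfg):
        m = make_model(phys, cfg)
        traj = m.run_to_steady_state(max_intervals=30)
        a, b = traj.window
        tau = 14 * 24.0
        assert traj.time[a] == pytest.approx((traj.n_intervals - 1) * tau)
        assert traj.time[b - 1] == pytest.approx(traj.n_intervals * tau)


class TestBatchEquivalence:
    def test_batch_matches_reference_solver(self, phys, cfg):
        kd = np.array([0.05, 9.0, 300.0])
        t0 = np.array([20.0, 1.0, 0.01])
        th = np.array([0.5, 10.0, 200.0])
        df = run_cohort_batch(kd, t0, th, form="soluble", dose_mg_kg=1.0,
                              interval_days=14.0, charge=0, phys=phys)
        for i in range(3):
            m = make_model(phys, cfg, kd=kd[i], t0=t0[i], t_half=th[i])
            rec = pk_endpoints(m.run_to_steady_state(max_intervals=30))
            assert df["cmin_nM"][i] == pytest.approx(rec.c_min, rel=1e-5)
            assert df["to_cmin_plasma"][i] == pytest.approx(
                rec.to_at_cmin, abs=1e-3)
            assert df["n_intervals"][i] == m.run_to_steady_state(
                max_intervals=30).n_intervals

    def test_occupancy_monotone_in_kd_and_dose(self, phys):
        """Steady-state trough TO is non-increasing in KD and
        non-decreasing in dose (5x5 grid)."""
        kd = np.geomspace(0.1, 100.0, 5)
        to = np.empty((5, 5))
        for j, dose in enumerate(np.geomspace(0.05, 20.0, 5)):
            df = run_cohort_batch(kd, np.full(5, 1.0), np.full(5, 10.0),
                                  form="soluble", dose_mg_kg=dose,
                                  interval_days=14.0, charge=0, phys=phys,
                                  sites=("plasma",))
            to[:, j] = df["to_cmin_plasma"].to_numpy()
        tol = 1e-6
        assert np.all(np.diff(to, axis=0) <= tol)    # KD up -> TO down
        assert np.all(np.diff(to, axis=1) >= -tol)   # dose up -> TO up
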