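"""Ionic-model unit and property tests, including the independent-oracle
comparisons of the 0D action potential."""

import numpy as np
import pytest

import cardiotwin.ttp_ionic as ti
from cardiotwin.ttp_ionic import CellType, IonicConductances
from oracles.ttp06_reference import run_ap, run_ap_rush_larsen


@pytest.fixture(scope="module")
def epi_ap():
    return ti.simulate_ap(CellType.EPI, duration=500.0, dt=0.02, fast=True)


class TestInitialState:
    def test_gates_in_unit_interval(self):
        for ct in CellType:
            st = ti.initial_state(ct)
            assert np.all(st.w >= 0) and np.all(st.w <= 1)
            assert np.all(st.z >= 0)

    def test_resting_quasi_equilibrium(self):
        st = ti.initial_state(CellType.EPI)
        I, dw, dz = ti.ionic_rates(st, CellType.EPI, IonicConductances())
        assert abs(float(I)) < 0.5

    def test_long_unpaced_relaxation_stays_near_rest(self):
        tr = ti.simulate_ap(CellType.EPI, pacing=ti.PacingProtocol(times=()),
                            duration=10_000.0, dt=0.05, fast=True, sample_every=10.0)
        assert -88.0 <= tr.V[-1] <= -84.0

    def test_epi_and_endo_rest_agree(self):
        tre = ti.simulate_ap(CellType.EPI, pacing=ti.PacingProtocol(times=()),
                             duration=2000.0, dt=0.05, fast=True, sample_every=10.0)
        trn = ti.simulate_ap(CellType.ENDO, pacing=ti.PacingProtocol(times=()),
                             duration=2000.0, dt=0.05, fast=True, sample_every=10.0)
        assert abs(tre.V[-1] - trn.V[-1]) < 1.0


class TestRates:
    def test_sodium_current_linear_in_conductance(self):
        st = ti.initial_state(CellType.EPI)
        st.V = np.array(-40.0)
        st.w[:3] = 0.5  # open sodium gates
        base = IonicConductances()
        doubled = IonicConductances(g_Na=2 * base.g_Na)
        _, terms1 = ti.currents(st.V, st.w, st.z, 0.294, 0.392, base.g_CaL, base.g_Na, base.g_Kr)
        _, terms2 = ti.currents(st.V, st.w, st.z, 0.294, 0.392, base.g_CaL, doubled.g_Na, base.g_Kr)
        assert terms2["I_Na"] == pytest.approx(2.0 * terms1["I_Na"], rel=1e-12)
        for k in ("I_CaL", "I_Kr", "I_K1"):
            assert terms2[k] == pytest.approx(terms1[k], rel=1e-12)

    @pytest.mark.parametrize("g_name", ["g_CaL", "g_Kr"])
    def test_other_conductances_scale_their_terms(self, g_name):
        st = ti.initial_state(CellType.EPI)
        st.V = np.array(0.0)
        st.w[:] = 0.5
        base = dict(g_CaL=3.98e-5, g_Na=14.838, g_Kr=0.153)
        scaled = dict(base)
        scaled[g_name] = 3.0 * base[g_name]
        term = {"g_CaL": "I_CaL", "g_Kr": "I_Kr"}[g_name]
        _, t1 = ti.currents(st.V, st.w, st.z, 0.294, 0.392, **base)
        _, t2 = ti.currents(st.V, st.w, st.z, 0.294, 0.392, **scaled)
        assert t2[term] == pytest.approx(3.0 * t1[term], rel=1e-12)

    def test_gate_rates_vanish_at_steady_state(self):
        st = ti.initial_state(CellType.EPI)
        inf, tau = ti.gates_inf_tau(st.V, st.z[..., 2], False)
        st.w[:] = inf
        _, dw, _ = ti.ionic_rates(st, CellType.EPI, IonicConductances())
        assert np.abs(dw).max() < 1e-14

    def test_nonfinite_state_raises(self):
        st = ti.initial_state(CellType.EPI)
        st.V = np.array(np.nan)
        with pytest.raises(FloatingPointError):
            ti.ionic_rates(st, CellType.EPI, IonicConductances())


class TestStepCell:
    def test_zero_dt_is_identity(self):
        st = ti.initial_state(CellType.EPI)
        out = ti.step_cell(st, 0.0, CellType.EPI, IonicConductances())
        assert np.array_equal(out.V, st.V)
        assert np.array_equal(out.w, st.w)
        assert np.array_equal(out.z, st.z)

    def test_equilibrium_persistence(self):
        st = ti.initial_state(CellType.EPI)
        v0 = float(st.V)
        for _ in range(1000):
            st = ti.step_cell(st, 0.05, CellType.EPI, IonicConductances())
        assert abs(float(st.V) - v0) < 0.5

    def test_stimulus_triggers_upstroke(self):
        st = ti.initial_state(CellType.EPI)
        c = IonicConductances()
        for k in range(int(5.0 / 0.02)):
            I = 52.0 if k * 0.02 < 1.0 else 0.0
            st = ti.step_cell(st, 0.02, CellType.EPI, c, I_app=I)
        assert float(st.V) > 10.0

    def test_gating_stays_in_unit_box_through_ap(self, epi_ap):
        assert epi_ap.w.min() >= 0.0 and epi_ap.w.max() <= 1.0


class TestActionPotential:
    def test_no_stimulus_no_excitation(self):
        tr = ti.simulate_ap(CellType.EPI, pacing=ti.PacingProtocol(times=()),
                            duration=600.0, dt=0.05, fast=True)
        assert np.abs(tr.V - tr.V[0]).max() < 1.0

    def test_mcell_apd_exceeds_epi(self, epi_ap):
        trm = ti.simulate_ap(CellType.MCELL, duration=500.0, dt=0.02, fast=True)
        assert ti.apd90(trm) > ti.apd90(epi_ap)

    def test_halving_gcal_shortens_apd(self, epi_ap):
        half = IonicConductances(g_CaL=0.5 * 3.98e-5)
        trh = ti.simulate_ap(CellType.EPI, cond=half, duration=500.0, dt=0.02, fast=True)
        assert ti.apd90(trh) < ti.apd90(epi_ap)

    def test_refractoriness(self):
        pacing = ti.PacingProtocol(times=(10.0, 60.0))
        tr = ti.simulate_ap(CellType.EPI, pacing=pacing, duration=400.0, dt=0.02, fast=True)
        # a second suprathreshold pulse 50 ms after upstroke must not
        # produce a second upstroke: count upward 0 mV crossings
        ups = np.sum((tr.V[:-1] < 0.0) & (tr.V[1:] >= 0.0))
        assert ups == 1


class TestOracleEquivalence:
    def test_transcription_matches_reference_at_same_scheme(self):
        """Both transcriptions integrated with the identical operator-split
        scheme agree to roundoff -> the equations match."""
        t_o, V_o = run_ap_rush_larsen("epi", duration=400.0, dt=0.02)
        tr = ti.simulate_ap(CellType.EPI, duration=400.0, dt=0.02)
        Vi = np.interp(t_o, tr.t, tr.V)
        assert np.abs(Vi - V_o).max() < 1e-9

    def test_fixed_step_converges_to_adaptive_reference(self):
        """At dt = 2.5 us the split scheme tracks the adaptively integrated
        reference to < 1 mV over the whole beat (upstroke included)."""
        t_o, V_o = run_ap("epi", duration=400.0)
        tr = ti.simulate_ap(CellType.EPI, duration=400.0, dt=0.0025, fast=True)
        Vi = np.interp(t_o, tr.t, tr.V)
        assert np.abs(Vi - V_o).max() < 1.0

    def test_table_path_matches_exact_path(self):
        tr_f = ti.simulate_ap(CellType.EPI, duration=400.0, dt=0.02, fast=True)
        tr_e = ti.simulate_ap(CellType.EPI, duration=400.0, dt=0.02)
        assert np.abs(tr_f.V - tr_e.V).max() < 0.05
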