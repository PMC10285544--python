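"""Cell-simulator contracts: determinism, boundary conditions, conservation,
serialization, and the qualitative physiology of the reference model."""

import numpy as np
import pytest

import cardiopop.cell_model as cm
from cardiopop.biomarkers import extract_biomarkers
from cardiopop.abnormality import detect_ap_abnormalities

from conftest import peak_force_last_cycle


SHORT = cm.SimulationConfig(n_cycles=5)


class TestTypes:
    def test_scaling_vector_bounds(self):
        with pytest.raises(ValueError):
            cm.ScalingVector(gNa=2.5)
        with pytest.raises(ValueError):
            cm.ScalingVector(gKr=-0.1)
        sv = cm.ScalingVector.from_array(np.linspace(0.0, 2.0, 11))
        assert np.allclose(sv.as_array(), np.linspace(0.0, 2.0, 11))

    def test_block_vector_bounds(self):
        with pytest.raises(ValueError):
            cm.DrugBlockVector(IKr=1.2)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            cm.MechanicalProtocol(mode="isometric", afterload=0.5)
        with pytest.raises(ValueError):
            cm.MechanicalProtocol(mode="afterloaded")
        with pytest.raises(ValueError):
            cm.MechanicalProtocol(initial_length=0.5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cm.SimulationConfig(n_cycles=1)
        with pytest.raises(ValueError):
            cm.SimulationConfig(sample_dt=0.7)  # does not divide 1000 ms

    def test_cell_state_roundtrip_bit_exact(self, ref_trace):
        st = ref_trace.final_state
        st2 = cm.CellState.from_json(st.to_json())
        assert st2 == st


class TestSimulate:
    def test_deterministic_bit_identical(self):
        a = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), SHORT)
        b = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), SHORT)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.Cai, b.Cai)
        assert np.array_equal(a.F_active, b.F_active)

    def test_isometric_length_constant(self, ref_trace):
        assert np.all(ref_trace.L == ref_trace.L[0])

    def test_returns_last_two_cycles_and_all_summaries(self, ref_trace, ref_config):
        n = int(round(ref_trace.cycle_length / ref_trace.sample_dt))
        assert ref_trace.V.size == 2 * n + 1
        assert ref_trace.summaries["APD90"].size == ref_config.n_cycles

    def test_zero_stimulus_no_ap(self, ref_trace):
        cfg = cm.SimulationConfig(n_cycles=2, stim_amplitude=0.0)
        tr = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), cfg,
                         initial_state=ref_trace.final_state)
        assert float(tr.V.max() - tr.V.min()) < 5.0
        assert extract_biomarkers(tr).flags.get("no_AP")

    def test_gkr_knockout_prolongs_or_flags(self, ref_trace):
        tr = cm.simulate(cm.ScalingVector(gKr=0.0), cm.MechanicalProtocol(),
                         cm.SimulationConfig())
        bm = extract_biomarkers(tr)
        flags = detect_ap_abnormalities(tr)
        ref_apd = extract_biomarkers(ref_trace).APD90
        prolonged = bm.APD90 is not None and bm.APD90 > ref_apd
        assert prolonged or flags.failed_repolarization or flags.EAD

    def test_calcium_conservation_with_frozen_membrane_fluxes(self, ref_trace):
        cfg = cm.SimulationConfig(n_cycles=2)
        tr = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), cfg,
                         initial_state=ref_trace.final_state,
                         _freeze_membrane_ca=True)
        vsr = cm.REFERENCE_PARAMS["vsr_ratio"]
        y0 = ref_trace.final_state.values
        y1 = tr.final_state.values
        tot0 = y0[7] + y0[11] + y0[8] / vsr
        tot1 = y1[7] + y1[11] + y1[8] / vsr
        assert abs(tot1 - tot0) / tot0 < 1e-8

    def test_step_halving_moves_apd90_below_tenth_ms(self):
        c1 = cm.SimulationConfig(n_cycles=5)
        c2 = cm.SimulationConfig(n_cycles=5, dt_fast=0.01, dt_slow=0.05)
        a = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), c1)
        b = cm.simulate(cm.ScalingVector(), cm.MechanicalProtocol(), c2)
        assert abs(a.summaries["APD90"][-1] - b.summaries["APD90"][-1]) < 0.1


class TestMechanics:
    def test_peak_force_increases_with_length(self, ref_trace, preload_traces):
        peaks = [peak_force_last_cycle(preload_traces[L]) for L in (0.80, 0.85, 0.90)]
        peaks.append(peak_force_last_cycle(ref_trace))
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_self_normalization(self, ref_trace):
        # reference peak at 0.93 L_max normalized by itself
        assert peak_force_last_cycle(ref_trace) == pytest.approx(1.0, abs=1e-3)

    def test_mechano_calcium_feedback_live(self, ref_trace, preload_traces):
        ca_short = float(preload_traces[0.80].Cai.max())
        ca_ref = float(ref_trace.Cai.max())
        assert abs(ca_short - ca_ref) / ca_ref > 0.01
        # shorter preload raises the free Ca2+ transient
        assert ca_short > ca_ref

    def test_afterload_one_is_isometric(self, ref_trace):
        tw = cm.afterloaded_twitch(cm.ScalingVector(), 1.0, baseline=ref_trace)
        assert np.all(tw.L == tw.L[0])

    def test_isotonic_phase_holds_total_force(self, afterloaded_traces):
        # the force clamp applies while the cell shortens; re-lengthening is
        # rate-limited by the rig and may fall below the load
        tw = afterloaded_traces[0.5]
        dL = np.gradient(tw.L, tw.sample_dt)
        shortening = dL < -1e-6
        assert shortening.any()
        held = tw.F_total[shortening]
        target = 0.5 * tw.meta["F_max"] + (tw.F_total[0] - tw.F_active[0])
        assert np.allclose(held, target, rtol=2e-2)

    def test_shortening_monotone_in_afterload(self, afterloaded_traces):
        amps, vels = [], []
        from cardiopop.biomarkers import shortening_metrics

        for a in (0.25, 0.5, 0.75):
            amp, vel = shortening_metrics(afterloaded_traces[a])
            amps.append(amp)
            vels.append(vel)
        assert amps[0] > amps[1] > amps[2] > 0
        assert vels[0] > vels[1] > vels[2] > 0

    def test_afterloaded_deterministic(self, ref_trace):
        a = cm.afterloaded_twitch(cm.ScalingVector(), 0.5, baseline=ref_trace)
        b = cm.afterloaded_twitch(cm.ScalingVector(), 0.5, baseline=ref_trace)
        assert np.array_equal(a.L, b.L)
        assert np.array_equal(a.F_total, b.F_total)

    def test_peak_isometric_force_repeatable(self):
        cfg = cm.SimulationConfig(n_cycles=5)
        v1 = cm.peak_isometric_force(cm.ScalingVector(), 0.93, cfg)
        v2 = cm.peak_isometric_force(cm.ScalingVector(), 0.93, cfg)
        assert v1 == v2


class TestExport:
    def test_csv_roundtrip(self, tmp_path, ref_trace):
        path = tmp_path / "trace.csv"
        ref_trace.to_csv(path)
        back = cm.Trace.from_csv(path, ref_trace.cycle_length)
        assert np.allclose(back.V, ref_trace.V)
        assert np.allclose(back.F_total, ref_trace.F_total)

    def test_npz_cache_matches_csv(self, tmp_path, ref_trace):
        ref_trace.to_npz(tmp_path / "trace.npz")
        dat = np.load(tmp_path / "trace.npz")
        assert np.array_equal(dat["V"], ref_trace.V)
        assert np.array_equal(dat["L"], ref_trace.L)
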