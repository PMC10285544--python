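"""Mechanical re-calibration staging: rejection attribution, conservation,
order independence.  The simulator is replaced by analytic fixture traces so
each stage's decision logic is exercised in isolation; the reference ODE
model's passage through all stages is covered by the acceptance suite.
"""

import numpy as np
import pytest

import cardiopop.mech_calibration as mc
from cardiopop.history_matching import PopulationRecord
from cardiopop.fixtures_and_toy import Segment, TraceFixtureSpec, make_trace

# behavior codes carried in the first scaling slot
HEALTHY = 1.0
BAD_FORCE = 0.11       # FTTP far too long
EAD_AT_SHORT = 0.12    # EAD appears at 0.80 L_max
FLAT_LF = 0.13         # peak force independent of length (tied L-F)
EAD_AT_LOW_AFT = 0.14  # EAD during the 0.25 F_max twitch
FLAT_FV = 0.15         # equal shortening velocities (non-monotone F-V)


def _ap_segments(bump=False):
    segs = [Segment(0.0, 2.0, -85.0, 35.0),
            Segment(2.0, 300.0, 35.0, -85.0, shape="cosine")]
    if bump:
        segs = [Segment(0.0, 2.0, -85.0, 35.0),
                Segment(2.0, 150.0, 35.0, -30.0, shape="cosine"),
                Segment(150.0, 160.0, -30.0, -10.0),
                Segment(160.0, 170.0, -10.0, -30.0),
                Segment(170.0, 300.0, -30.0, -85.0, shape="cosine")]
    return segs


def _force_segments(amp, fttp_ok=True):
    if fttp_ok:
        return [Segment(50.0, 325.0, 0.0, amp),       # FTTP = 275 ms
                Segment(325.0, 660.0, amp, 0.0)]
    return [Segment(50.0, 500.0, 0.0, amp),           # FTTP = 450 ms (too long)
            Segment(500.0, 840.0, amp, 0.0)]


def _ca_segments():
    return [Segment(5.0, 60.0, 0.1, 1.0),
            Segment(60.0, 300.0, 1.0, 0.1, shape="cosine")]


def fake_simulate(sv, protocol, config=None, block=None, **kw):
    code = round(float(sv.gNa), 2)
    L = protocol.initial_length
    amp_by_len = {0.80: 0.4, 0.85: 0.6, 0.90: 0.8, 0.93: 1.0}
    amp = 1.0 if code == FLAT_LF else amp_by_len[round(L, 2)]
    bump = (code == EAD_AT_SHORT and round(L, 2) == 0.80)
    tr = make_trace(TraceFixtureSpec(
        n_cycles=2,
        baseline={"V": -85.0, "Cai": 0.1, "F_active": 0.0, "L": L},
        segments={"V": _ap_segments(bump=bump),
                  "Cai": _ca_segments(),
                  "F_active": _force_segments(amp, fttp_ok=(code != BAD_FORCE))}))
    tr.meta["code"] = code
    return tr


def fake_afterloaded_twitch(sv, afterload_fraction, config=None, block=None,
                            *, baseline=None, **kw):
    code = round(float(sv.gNa), 2)
    depth = 0.05 if code == FLAT_FV else 0.3 * (1.0 - afterload_fraction)
    dur = 200.0 if code == FLAT_FV else 100.0 + 200.0 * afterload_fraction
    bump = (code == EAD_AT_LOW_AFT and afterload_fraction == 0.25)
    tr = make_trace(TraceFixtureSpec(
        n_cycles=1,
        baseline={"V": -85.0, "Cai": 0.1, "F_active": afterload_fraction, "L": 0.93},
        segments={"V": _ap_segments(bump=bump),
                  "Cai": _ca_segments(),
                  "L": [Segment(100.0, 100.0 + dur, 0.93, 0.93 * (1 - depth)),
                        Segment(100.0 + dur, 800.0, 0.93 * (1 - depth), 0.93)]}))
    tr.status = "ok"
    return tr


def make_population(codes):
    recs = []
    for i, code in enumerate(codes):
        scaling = np.ones(11)
        scaling[0] = code
        recs.append(PopulationRecord(model_id=i, scaling=scaling))
    return recs


@pytest.fixture(autouse=True)
def patch_simulators(monkeypatch):
    monkeypatch.setattr(mc, "simulate", fake_simulate)
    monkeypatch.setattr(mc, "afterloaded_twitch", fake_afterloaded_twitch)


class TestStages:
    def test_empty_population(self):
        rep = mc.stage_force_biomarkers([])
        assert rep.models_in == 0 and rep.rejected == {}

    def test_force_biomarker_rejection(self):
        pop = make_population([HEALTHY, BAD_FORCE])
        rep = mc.stage_force_biomarkers(pop)
        assert list(rep.rejected) == [1]
        assert "FTTP" in rep.rejected[1]
        assert pop[1].status == "rejected:force_biomarkers"

    def test_preload_abnormality_rejection(self):
        pop = make_population([HEALTHY, EAD_AT_SHORT])
        rep = mc.stage_preload(pop)
        assert list(rep.rejected) == [1]
        assert "0.8" in rep.rejected[1] and "EAD" in rep.rejected[1]

    def test_preload_empty_lengths_noop(self):
        pop = make_population([HEALTHY])
        rep = mc.stage_preload(pop, lengths=())
        assert rep.rejected == {}

    def test_lf_monotone_kept_flat_rejected(self):
        pop = make_population([HEALTHY, FLAT_LF])
        mc.stage_preload(pop)
        rep = mc.stage_lf_curve(pop)
        assert list(rep.rejected) == [1]
        assert rep.rejected[1] == "non_monotone_LF"
        # healthy curve normalized to the reference length
        curve = dict(rep.curves[0])
        assert curve[0.93] == pytest.approx(1.0)
        vals = [v for _, v in sorted(rep.curves[0])]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_lf_tie_counts_as_failure(self):
        pop = make_population([HEALTHY])
        pop[0].flags["preload_peaks"] = {0.80: 0.5, 0.85: 0.5, 0.90: 0.8, 0.93: 1.0}
        rep = mc.stage_lf_curve(pop)
        assert rep.rejected == {0: "non_monotone_LF"}

    def test_afterload_abnormality_and_fv(self):
        pop = make_population([HEALTHY, EAD_AT_LOW_AFT, FLAT_FV])
        rep = mc.stage_afterload(pop)
        assert set(rep.rejected) == {1, 2}
        assert "EAD" in rep.rejected[1]
        assert rep.rejected[2] == "non_monotone_FV"
        vels = [v for _, v in rep.curves[0]]
        assert all(a > b for a, b in zip(vels, vels[1:]))


class TestPipeline:
    def test_rejections_attributed_to_correct_stages(self):
        pop = make_population([HEALTHY, BAD_FORCE, EAD_AT_SHORT, FLAT_LF,
                               EAD_AT_LOW_AFT])
        accepted, reports = mc.run_mechanical_calibration(pop)
        by_stage = {r.stage: list(r.rejected) for r in reports}
        assert by_stage["force_biomarkers"] == [1]
        assert by_stage["preload"] == [2]
        assert by_stage["LF_curve"] == [3]
        assert by_stage["afterload"] == [4]
        assert [r.model_id for r in accepted] == [0]

    def test_conservation(self):
        pop = make_population([HEALTHY, HEALTHY, BAD_FORCE, FLAT_LF, FLAT_FV])
        accepted, reports = mc.run_mechanical_calibration(pop)
        total_rejected = sum(len(r.rejected) for r in reports)
        assert len(accepted) + total_rejected == len(pop)

    def test_rejected_never_reenter(self):
        pop = make_population([BAD_FORCE])
        accepted, reports = mc.run_mechanical_calibration(pop)
        assert pop[0].status == "rejected:force_biomarkers"
        assert all(r.models_in == 0 for r in reports[1:])

    def test_order_independence_within_stage(self):
        pop_a = make_population([HEALTHY, BAD_FORCE, EAD_AT_SHORT])
        pop_b = make_population([EAD_AT_SHORT, HEALTHY, BAD_FORCE])
        _, rep_a = mc.run_mechanical_calibration(pop_a)
        _, rep_b = mc.run_mechanical_calibration(pop_b)
        codes_a = {round(pop_a[m].scaling[0], 2) for r in rep_a for m in r.rejected}
        codes_b = {round(pop_b[m].scaling[0], 2) for r in rep_b for m in r.rejected}
        assert codes_a == codes_b

    def test_stage_report_frame(self):
        pop = make_population([BAD_FORCE])
        rep = mc.stage_force_biomarkers(pop)
        df = rep.to_frame()
        assert list(df.columns) == ["model_id", "stage", "decision", "reason"]
        assert df.iloc[0]["decision"] == "rejected"
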