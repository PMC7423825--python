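"""PV-loop analysis: segmentation, fiducials, energetics, ESPVR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bivent import AnimalModel, pv
from bivent.errors import (
    DegenerateFitError,
    FiducialError,
    InsufficientBeatsError,
    InvalidBeatError,
    OpenLoopError,
    SegmentationError,
)
from bivent.sim import activation, simulate
from conftest import occlusion_beat_family


def rectangle_beat(v_lo=100.0, v_hi=150.0, p_lo=10.0, p_hi=100.0, n_edge=50, fs=250.0):
    """Counter-clockwise rectangular loop starting at the ED corner
    (high volume, low pressure)."""
    v = np.concatenate([
        np.full(n_edge, v_hi),                      # isovolumic pressurisation
        np.linspace(v_hi, v_lo, n_edge),            # ejection at p_hi
        np.full(n_edge, v_lo),                      # isovolumic relaxation
        np.linspace(v_lo, v_hi, n_edge),            # filling at p_lo
    ])
    p = np.concatenate([
        np.linspace(p_lo, p_hi, n_edge),
        np.full(n_edge, p_hi),
        np.linspace(p_hi, p_lo, n_edge),
        np.full(n_edge, p_lo),
    ])
    return pv.Beat(p=p, v=v, fs=fs)


class TestSegmentation:
    @pytest.fixture(scope="class")
    def hr75_run(self):
        d = AnimalModel().to_dict()
        d["heart_rate"] = 75.0
        d["lv_sensor"]["noise_sd"] = 0.0
        d["rv_sensor"]["noise_sd"] = 0.0
        m = AnimalModel.from_dict(d)
        return simulate(m, 30.0, settle=15.0)

    def test_beat_count_matches_heart_rate(self, hr75_run):
        beats = pv.segment_beats(hr75_run.channels["P_LV"],
                                 hr75_run.channels["V_LV"], hr75_run.fs)
        # 30 s at 75 bpm = 37.5 cycles; partial first/last discarded
        assert 35 <= len(beats) <= 38

    def test_constant_signals_rejected(self):
        flat = np.full(5000, 50.0)
        with pytest.raises(SegmentationError):
            pv.segment_beats(flat, flat, 250.0)

    def test_invariant_to_pressure_offset(self, hr75_run):
        p = hr75_run.channels["P_LV"]
        v = hr75_run.channels["V_LV"]
        a = pv.segment_beats(p, v, hr75_run.fs)
        b = pv.segment_beats(p + 40.0, v, hr75_run.fs)
        assert len(a) == len(b)
        assert all(x.t0 == y.t0 for x, y in zip(a, b))


class TestFiducials:
    def test_rectangle_corners(self):
        beat = rectangle_beat()
        f = pv.detect_fiducials(beat, v0_ref=0.0)
        assert f.ed_volume == pytest.approx(150.0)
        assert f.ed_pressure == pytest.approx(10.0, abs=2.0)
        assert f.es_volume == pytest.approx(100.0)
        assert f.es_pressure == pytest.approx(100.0, abs=2.0)

    def test_circular_shift_equivariance(self):
        # tie-free loop (ellipse) so the argmax rules have unique winners
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        beat = pv.Beat(p=60 - 45 * np.sin(th), v=140 + 35 * np.cos(th), fs=250.0)
        f0 = pv.detect_fiducials(beat, v0_ref=0.0)
        k = 157
        shifted = pv.Beat(p=np.roll(beat.p, k), v=np.roll(beat.v, k), fs=beat.fs)
        fk = pv.detect_fiducials(shifted, v0_ref=0.0)
        n = beat.p.size
        assert (f0.ed_index + k) % n == fk.ed_index
        assert (f0.es_index + k) % n == fk.es_index

    def test_v0_above_volume_range_rejected(self):
        beat = rectangle_beat()
        with pytest.raises(FiducialError):
            pv.detect_fiducials(beat, v0_ref=120.0)

    def test_es_at_maximal_elastance_on_simulator_beat(self, quiet_baseline_ss, quiet_model):
        """With v0_ref = 0 the detected ES lies within 2 samples of the
        known activation peak of the elastance drive."""
        ss = quiet_baseline_ss
        beats = pv.segment_beats(ss.channels["P_LV"], ss.channels["V_LV"], ss.fs)
        period = ss.meta["period"]
        grid = np.linspace(0, period, 2000, endpoint=False)
        acts = [activation(t, period, quiet_model.lv) for t in grid]
        t_peak = grid[int(np.argmax(acts))]
        b = beats[len(beats) // 2]
        f = pv.detect_fiducials(b, v0_ref=0.0)
        # beat starts at ED (phase of the previous activation cycle end)
        t_es_in_cycle = (b.t0 + f.es_index / ss.fs) % period
        dist = min(abs(t_es_in_cycle - t_peak), period - abs(t_es_in_cycle - t_peak))
        assert dist <= 2.5 / ss.fs


class TestStrokeWork:
    def test_rectangle_area(self):
        assert pv.stroke_work(rectangle_beat()) == pytest.approx(50.0 * 90.0, rel=1e-9)

    def test_ellipse_area_matches_pi_a_b(self):
        th = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        a_ax, b_ax = 25.0, 40.0
        beat = pv.Beat(p=60 + b_ax * np.sin(th), v=120 + a_ax * np.cos(th), fs=250.0)
        assert pv.stroke_work(beat) == pytest.approx(np.pi * a_ax * b_ax, rel=0.005)

    def test_orientation_independent(self):
        beat = rectangle_beat()
        rev = pv.Beat(p=beat.p[::-1].copy(), v=beat.v[::-1].copy(), fs=beat.fs)
        assert pv.stroke_work(rev) == pytest.approx(pv.stroke_work(beat), rel=1e-12)

    def test_open_loop_rejected(self):
        v = np.linspace(100, 150, 60)
        p = np.linspace(10, 90, 60)
        with pytest.raises(OpenLoopError):
            pv.stroke_work(pv.Beat(p=p, v=v, fs=250.0))

    def test_shoelace_matches_trapezoid_integral_on_simulator_beats(self, quiet_baseline_ss):
        """Two independent area computations agree to 0.1%."""
        ss = quiet_baseline_ss
        beats = pv.segment_beats(ss.channels["P_LV"], ss.channels["V_LV"], ss.fs)
        for b in beats[2:8]:
            vc = np.append(b.v, b.v[0])
            pc = np.append(b.p, b.p[0])
            trap = abs(np.trapezoid(pc, vc))
            assert pv.stroke_work(b) == pytest.approx(trap, rel=1e-3)

    @settings(deadline=None, max_examples=25)
    @given(w=st.floats(5.0, 120.0), h=st.floats(5.0, 150.0), k=st.integers(0, 199))
    def test_rotated_rectangle_area(self, w, h, k):
        beat = rectangle_beat(v_lo=100.0, v_hi=100.0 + w, p_lo=5.0, p_hi=5.0 + h)
        rolled = pv.Beat(p=np.roll(beat.p, k), v=np.roll(beat.v, k), fs=beat.fs)
        assert pv.stroke_work(rolled) == pytest.approx(w * h, rel=1e-9)


class TestEnergetics:
    def test_potential_energy_triangle(self):
        assert pv.potential_energy(90.0, 120.0, 20.0) == pytest.approx(4500.0)

    def test_potential_energy_degenerate(self):
        assert pv.potential_energy(90.0, 20.0, 20.0) == 0.0

    def test_potential_energy_floored_with_warning(self):
        with pytest.warns(UserWarning):
            assert pv.potential_energy(90.0, 10.0, 20.0) == 0.0

    def test_arterial_elastance(self):
        assert pv.arterial_elastance(90.0, 60.0) == pytest.approx(1.5)
        assert pv.arterial_elastance(27.0, 67.5) == pytest.approx(0.4)
        assert pv.arterial_elastance(90.0, 30.0) == pytest.approx(2 * pv.arterial_elastance(90.0, 60.0))

    def test_arterial_elastance_rejects_nonpositive_sv(self):
        with pytest.raises(InvalidBeatError):
            pv.arterial_elastance(90.0, 0.0)

    def test_coupling_ratio(self):
        assert pv.coupling_ratio(0.38, 0.29) == pytest.approx(0.38 / 0.29)
        assert pv.coupling_ratio(0.5, 0.5) == 1.0
        with pytest.raises(DegenerateFitError):
            pv.coupling_ratio(1.0, 0.0)


class TestESPVR:
    @staticmethod
    def line_family(ees=0.5, vo=30.0, edvs=(180, 170, 160, 150, 140, 130)):
        """Small loops whose upper-left corners lie exactly on
        P = ees * (V - vo)."""
        beats = []
        for edv in edvs:
            esv = edv - 40.0
            esp = ees * (esv - vo)
            beats.append(rectangle_beat(v_lo=esv, v_hi=edv, p_lo=3.0, p_hi=esp))
        return beats

    def test_exact_line_recovered_in_two_iterations(self):
        fit = pv.fit_espvr(self.line_family())
        assert fit.ees == pytest.approx(0.5, abs=1e-6)
        assert fit.vo == pytest.approx(30.0, abs=1e-4)
        assert fit.iterations <= 2
        assert fit.converged

    def test_too_few_beats_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            pv.fit_espvr(self.line_family(edvs=(180, 170, 160, 150)))

    def test_flat_preload_rejected(self):
        with pytest.raises((DegenerateFitError, InsufficientBeatsError)):
            pv.fit_espvr([rectangle_beat() for _ in range(6)])

    def test_simulator_ground_truth_recovery(self):
        """Noise-free occlusion run on a chamber with Emax 0.83, V0 20:
        the fit recovers both within the stated tolerances."""
        from bivent.sim import ivc_occlusion_maneuver

        d = AnimalModel().to_dict()
        d["lv"].update(emax=0.83, v0=20.0)
        d["lv_sensor"]["noise_sd"] = 0.0
        d["rv_sensor"]["noise_sd"] = 0.0
        m = AnimalModel.from_dict(d)
        occ = ivc_occlusion_maneuver(m, settle=22.0)
        fam = occlusion_beat_family(occ, "LV")
        fit = pv.fit_espvr(fam)
        assert fit.ees == pytest.approx(0.83, rel=0.05)
        assert abs(fit.vo - 20.0) < 5.0


class TestBeatIndices:
    def test_rectangle_toy_values(self):
        """SW 4500, PE 5000, PVA 9500, PVA x HR 570000 for the toy loop."""
        beat = rectangle_beat(v_lo=100.0, v_hi=150.0, p_lo=10.0, p_hi=100.0)
        espvr = pv.ESPVRFit(ees=1.0, vo=0.0, es_points=np.empty((0, 2)),
                            r2=1.0, iterations=1, converged=True)
        bi = pv.beat_indices(beat, espvr=espvr, heart_rate=60.0)
        assert bi.sw == pytest.approx(4500.0, rel=1e-6)
        assert bi.pe == pytest.approx(bi.esp * bi.esv / 2.0)
        assert bi.pva == bi.sw + bi.pe
        assert bi.pva_hr == pytest.approx(bi.pva * 60.0)

    def test_pva_identity_and_ea_closure_on_simulator_beats(self, quiet_baseline_ss):
        ss = quiet_baseline_ss
        beats = pv.segment_beats(ss.channels["P_LV"], ss.channels["V_LV"], ss.fs)
        espvr = pv.ESPVRFit(ees=0.8, vo=10.0, es_points=np.empty((0, 2)),
                            r2=1.0, iterations=1, converged=True)
        for b in beats[2:8]:
            bi = pv.beat_indices(b, espvr=espvr)
            assert bi.pva == bi.sw + bi.pe
            assert bi.ea * bi.sv == pytest.approx(bi.esp, rel=1e-12)

    def test_indices_invariant_to_sampling_rate(self, quiet_model):
        """Doubling the sampling rate moves every index by < 1%."""
        out = {}
        for fs in (250.0, 500.0):
            ss = simulate(quiet_model, 10.0, settle=20.0, fs=fs)
            beats = pv.segment_beats(ss.channels["P_LV"], ss.channels["V_LV"], fs)
            espvr = pv.ESPVRFit(ees=0.8, vo=10.0, es_points=np.empty((0, 2)),
                                r2=1.0, iterations=1, converged=True)
            idx = [pv.beat_indices(b, espvr=espvr) for b in beats[-6:]]
            out[fs] = {k: np.median([getattr(i, k) for i in idx])
                       for k in ("edv", "esv", "esp", "sw", "pe", "pva", "ea")}
        for k in out[250.0]:
            assert out[500.0][k] == pytest.approx(out[250.0][k], rel=0.01), k
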