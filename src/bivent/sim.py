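"""Closed-loop biventricular circulation simulator.

Generates the synthetic inputs the analysis pipeline assumes: simultaneous
LV/RV pressure and raw conductance channels, aortic / pulmonary-artery /
central-venous pressures, pump flow, and the two measurement manoeuvres
(inferior-vena-cava occlusion and hypertonic-saline bolus), plus the
interventions of the four-stage shock protocol (stepwise microsphere shock,
transvalvular pump support, norepinephrine infusion).
"""

from __future__ import annotations

import hashlib
import json
import math
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _engine as eng
from .errors import (
    InvalidParameterError,
    IntegrationError,
    PhysiologyViolationError,
    ShockInductionFailure,
    CohortSamplingError,
    InsufficientBeatsError,
)
from .params import (
    AnimalModel,
    ChamberParams,
    ImpellaParams,
    NEParams,
    O2Params,
    ShockParams,
)
from .signals import SignalSet

DT_DEFAULT = 2.0e-4  # s, RK4 step
FS_DEFAULT = 250.0  # Hz, recording rate
VALVE_WIDTH = 0.25  # mmHg, soft-diode smoothing


# ---------------------------------------------------------------------------
# activation waveform
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _activation_norm(tau1: float, tau2: float, n1: float, n2: float) -> float:
    """Peak of the unnormalised double-Hill waveform on the unit period."""
    x = np.linspace(0.0, 1.0, 8193)[:-1]
    h1 = (x / tau1) ** n1
    h1 = h1 / (1.0 + h1)
    h2 = 1.0 / (1.0 + (x / tau2) ** n2)
    a = h1 * h2
    i = int(np.argmax(a))
    if i == 0 or i == a.size - 1:
        return float(a[i])
    # refine to machine precision around the grid peak
    from scipy.optimize import minimize_scalar

    def neg(xx):
        u = (xx / tau1) ** n1
        return -(u / (1.0 + u)) / (1.0 + (xx / tau2) ** n2)

    res = minimize_scalar(neg, bounds=(x[i - 1], x[i + 1]), method="bounded",
                          options={"xatol": 1e-14})
    return float(max(a[i], -res.fun))


def activation(t_in_beat: float, period: float, shape: ChamberParams) -> float:
    """Normalised activation in [0, 1] at time ``t_in_beat`` of a beat.

    Double-Hill drive: a rising Hill function times a falling one, peak
    normalised to exactly 1 over the beat.  Starts relaxed (value < 0.05 at
    t = 0).
    """
    if period <= 0:
        raise InvalidParameterError(f"period must be positive, got {period}")
    if not 0 <= t_in_beat < period:
        raise InvalidParameterError("t_in_beat must satisfy 0 <= t < period")
    x = t_in_beat / period
    h1 = (x / shape.act_tau1) ** shape.act_n1
    h1 = h1 / (1.0 + h1)
    h2 = 1.0 / (1.0 + (x / shape.act_tau2) ** shape.act_n2)
    norm = _activation_norm(shape.act_tau1, shape.act_tau2, shape.act_n1, shape.act_n2)
    return float(h1 * h2 / norm)


# ---------------------------------------------------------------------------
# effective parameters and engine vector
# ---------------------------------------------------------------------------

def _ne_scale(eff: float, dose: float, d50: float) -> float:
    """Saturating (Emax-model) multiplicative dose-response."""
    return 1.0 + eff * dose / (dose + d50) if dose > 0 else 1.0


def effective_heart_rate(model: AnimalModel) -> float:
    """Heart rate after the norepinephrine chronotropic effect (bpm)."""
    return model.heart_rate * _ne_scale(model.ne.eff_hr, model.ne.dose, model.ne.d50)


def build_pvec(model: AnimalModel, occlusion: Optional[Tuple[float, float, float]] = None) -> np.ndarray:
    """Pack a model (with NE effects applied) into the engine vector.

    occlusion = (t_start, ramp_duration, resistance_multiplier) on the
    systemic venous return path, or None.
    """
    d = model.ne.dose
    p = np.zeros(eng.NPAR)
    hr = effective_heart_rate(model)
    p[eng.P_T] = 60.0 / hr
    for base, ch, eff_emax in (
        (eng.P_LV, model.lv, model.ne.eff_lv_emax),
        (eng.P_RV, model.rv, model.ne.eff_rv_emax),
    ):
        p[base + 0] = ch.emax * _ne_scale(eff_emax, d, model.ne.d50)
        p[base + 1] = ch.emin
        p[base + 2] = ch.v0
        p[base + 3] = ch.act_tau1
        p[base + 4] = ch.act_tau2
        p[base + 5] = ch.act_n1
        p[base + 6] = ch.act_n2
        p[base + 7] = 1.0 / _activation_norm(ch.act_tau1, ch.act_tau2, ch.act_n1, ch.act_n2)
    c = model.circuit
    p[eng.P_R_AV] = c.r_av
    p[eng.P_R_SART] = c.r_sys_art * _ne_scale(model.ne.eff_svr, d, model.ne.d50)
    p[eng.P_R_SVEN] = c.r_sys_ven
    p[eng.P_R_TV] = c.r_tv
    p[eng.P_R_PVALVE] = c.r_pv
    p[eng.P_R_PART] = c.r_pul_art * _ne_scale(model.ne.eff_pvr, d, model.ne.d50)
    p[eng.P_R_PVEN] = c.r_pul_ven
    p[eng.P_R_MV] = c.r_mv
    p[eng.P_C_SA] = c.c_sys_art
    p[eng.P_C_SV] = c.c_sys_ven
    p[eng.P_C_PA] = c.c_pul_art
    p[eng.P_C_PV] = c.c_pul_ven
    p[eng.P_VU_SA] = c.vu_sys_art
    p[eng.P_VU_SV] = c.vu_sys_ven * _ne_scale(model.ne.eff_venous_unstressed, d, model.ne.d50)
    p[eng.P_VU_PA] = c.vu_pul_art
    p[eng.P_VU_PV] = c.vu_pul_ven
    p[eng.P_INFUSION] = c.infusion_rate / 3600.0
    p[eng.P_PERI_GAIN] = model.pericardium.gain
    p[eng.P_PERI_K] = model.pericardium.steepness
    p[eng.P_PERI_VREF] = model.pericardium.v_ref
    p[eng.P_PUMP_ON] = 1.0 if model.pump.enabled else 0.0
    p[eng.P_PUMP_MAX] = model.pump.max_flow * 1000.0 / 60.0
    p[eng.P_PUMP_SLOPE] = model.pump.head_slope
    p[eng.P_PUMP_VSUC] = model.pump.suction_volume
    p[eng.P_PUMP_WSUC] = model.pump.suction_width
    if occlusion is None:
        p[eng.P_OCC_T0] = 0.0
        p[eng.P_OCC_DUR] = 1.0
        p[eng.P_OCC_MULT] = 1.0
    else:
        p[eng.P_OCC_T0], p[eng.P_OCC_DUR], p[eng.P_OCC_MULT] = occlusion
    p[eng.P_VALVE_W] = VALVE_WIDTH
    return p


def initial_state(model: AnimalModel) -> np.ndarray:
    """Heuristic physiological starting state honouring total blood volume."""
    c = model.circuit
    p_sa, p_sv, p_pa, p_pv = 70.0, 8.0, 20.0, 12.0
    v_lv, v_rv = 150.0, 150.0
    for _ in range(30):
        peri = model.pericardium.gain * math.exp(
            model.pericardium.steepness * (v_lv + v_rv - model.pericardium.v_ref)
        )
        v_lv = model.lv.v0 + max(p_pv - peri, 1.0) / model.lv.emin
        v_rv = model.rv.v0 + max(p_sv - peri, 1.0) / model.rv.emin
    d = model.ne.dose
    vu_sv = c.vu_sys_ven * _ne_scale(model.ne.eff_venous_unstressed, d, model.ne.d50)
    v_sa = c.vu_sys_art + c.c_sys_art * p_sa
    v_pa = c.vu_pul_art + c.c_pul_art * p_pa
    v_pv = c.vu_pul_ven + c.c_pul_ven * p_pv
    v_sv = c.total_volume - (v_lv + v_rv + v_sa + v_pa + v_pv)
    if v_sv <= vu_sv * 0.2:
        raise InvalidParameterError("total blood volume too small for the configured circuit")
    return np.array([v_lv, v_rv, v_sa, v_sv, v_pa, v_pv])


def config_hash(model: AnimalModel) -> str:
    blob = json.dumps(model.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate(
    model: AnimalModel,
    duration: float,
    events: Optional[Sequence[Tuple[float, str]]] = None,
    *,
    settle: float = 0.0,
    dt: float = DT_DEFAULT,
    fs: float = FS_DEFAULT,
    occlusion: Optional[Tuple[float, float, float]] = None,
    saline: Optional[Tuple[float, float, float]] = None,
    y0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> SignalSet:
    """Integrate the closed loop and return a recorded SignalSet.

    ``settle`` seconds are integrated before t=0 without recording (warm-up
    to periodic steady state).  ``occlusion``/``saline`` describe the two
    measurement manoeuvres (times relative to the recorded window):
    occlusion = (t0, ramp_duration, multiplier) on venous-return resistance;
    saline = (t0, transient_duration, conductivity_gain) acting on the
    conductance channels only.
    """
    period = 60.0 / effective_heart_rate(model)
    if duration < 10 * period:
        raise InvalidParameterError(
            f"duration {duration} s is shorter than 10 beats ({10 * period:.2f} s)"
        )
    rec_every = int(round(1.0 / (fs * dt)))
    if abs(rec_every * dt * fs - 1.0) > 1e-9:
        raise InvalidParameterError("1/fs must be an integer multiple of dt")
    y = initial_state(model) if y0 is None else np.asarray(y0, dtype=float).copy()

    if settle > 0:
        p_settle = build_pvec(model, occlusion=None)
        n = int(round(settle / dt))
        _, _, _, y, ok = eng.integrate(y, p_settle, -settle, dt, n, n)
        if not ok:
            raise PhysiologyViolationError("negative chamber volume during settle phase")

    p = build_pvec(model, occlusion=occlusion)
    n_steps = int(round(duration / dt))
    t, states, chans, y_final, ok = eng.integrate(y, p, 0.0, dt, n_steps, rec_every)
    if not ok:
        raise PhysiologyViolationError("negative chamber volume during simulation")
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state encountered", last_state=y_final, last_time=t[-1])

    v_lv = states[:, 0]
    v_rv = states[:, 1]
    cum_q_pv = states[:, 6] - states[0, 6]
    cum_q_sys = states[:, 7] - states[0, 7]
    if rng is None:
        rng = np.random.default_rng(model.seed)

    # conductance channels: G = alpha * (g(t) * V_true + Vp) + alpha * noise
    g = np.ones_like(t)
    annotations: List[Tuple[float, str]] = list(events or [])
    if saline is not None:
        t0, dur, gain = saline
        g = 1.0 + (gain - 1.0) * _saline_profile(t, t0, dur)
        annotations.append((float(t0), "saline_bolus_start"))
        annotations.append((float(t0 + dur), "saline_bolus_end"))
    g_lv = model.lv_sensor.alpha * (g * v_lv + model.lv_sensor.parallel_volume)
    g_rv = model.rv_sensor.alpha * (g * v_rv + model.rv_sensor.parallel_volume)
    if model.lv_sensor.noise_sd > 0:
        g_lv = g_lv + model.lv_sensor.alpha * model.lv_sensor.noise_sd * rng.standard_normal(t.size)
    if model.rv_sensor.noise_sd > 0:
        g_rv = g_rv + model.rv_sensor.alpha * model.rv_sensor.noise_sd * rng.standard_normal(t.size)

    if occlusion is not None:
        annotations.append((float(occlusion[0]), "occlusion_start"))
        annotations.append((float(occlusion[0] + occlusion[1]), "occlusion_end"))

    # suction annotations: pump output materially below its head-curve value
    if model.pump.enabled:
        s = 1.0 / (1.0 + np.exp(-(v_lv - model.pump.suction_volume) / model.pump.suction_width))
        in_suction = s < 0.95
        starts = np.flatnonzero(np.diff(in_suction.astype(int)) == 1)
        if in_suction[0]:
            starts = np.concatenate([[0], starts])
        for i in starts:
            annotations.append((float(t[i]), "suction"))

    channels = {
        "P_LV": chans[:, 0],
        "P_RV": chans[:, 1],
        "P_AO": chans[:, 2],
        "P_PA": chans[:, 3],
        "P_CV": chans[:, 4],
        "V_LV": v_lv,
        "V_RV": v_rv,
        "G_LV": g_lv,
        "G_RV": g_rv,
        "Q_pump": chans[:, 5],
    }
    period = p[eng.P_T]
    extras = {
        "q_av": chans[:, 6],
        "q_pv": chans[:, 7],
        "q_mv": chans[:, 8],
        "p_peri": chans[:, 9],
        "cum_q_pv": cum_q_pv,
        "cum_q_sys": cum_q_sys,
        "states": states,
        "total_volume": states[:, :6].sum(axis=1),
        "y_final": y_final,
    }
    meta = {
        "seed": int(model.seed),
        "config_hash": config_hash(model),
        "heart_rate": 60.0 / period,
        "period": period,
        "ne_dose": model.ne.dose,
        "dt": dt,
    }
    ss = SignalSet(fs=fs, time=t, channels=channels,
                   annotations=sorted(annotations), meta=meta, extras=extras)
    ss.meta["co"] = mean_co(ss)
    ss.meta["svo2"] = fick_svo2(ss.meta["co"], model.o2) if ss.meta["co"] > 0 else 0.0
    ss.meta["map"] = float(np.mean(_last_beats(ss, channels["P_AO"], 10)))
    return ss


def _saline_profile(t: np.ndarray, t0: float, dur: float) -> np.ndarray:
    """Smooth conductivity transient: smoothstep rise, exponential washout."""
    rise = dur / 3.0
    tau = dur / 1.5
    x = np.clip((t - t0) / rise, 0.0, 1.0)
    up = x * x * (3.0 - 2.0 * x)
    decay = np.where(t > t0 + rise, np.exp(-(t - t0 - rise) / tau), 1.0)
    return np.where(t < t0, 0.0, up * decay)


def _last_beats(ss: SignalSet, arr: np.ndarray, n_beats: int) -> np.ndarray:
    n = int(round(n_beats * ss.meta["period"] * ss.fs))
    return arr[-n:] if n < arr.size else arr


def mean_co(ss: SignalSet, n_beats: int = 10, window: Optional[Tuple[float, float]] = None) -> float:
    """Mean pulmonary flow, L/min (thermodilution / Swan-Ganz surrogate):
    true simulated flow through the pulmonary valve, which in a series
    circulation equals systemic output (pump plus aortic valve) at steady
    state.  Uses the last ``n_beats`` beats, or an explicit time window.
    """
    cum = ss.extras["cum_q_pv"]
    period = ss.meta["period"]
    if window is not None:
        # snap to a whole number of beats so the pulsatile flow is not
        # truncated mid-cycle
        n = max(1, int((window[1] - window[0]) / period))
        i1 = min(int(np.searchsorted(ss.time, window[1])), ss.time.size - 1)
        i0 = max(0, i1 - int(round(n * period * ss.fs)))
    else:
        i1 = ss.time.size - 1
        i0 = max(0, i1 - int(round(n_beats * period * ss.fs)))
    q_mean = (cum[i1] - cum[i0]) / (ss.time[i1] - ss.time[i0])
    return float(q_mean) * 60.0 / 1000.0


def steady_state_error(ss: SignalSet, n_beats: int = 5) -> float:
    """Max relative beat-to-beat change of LV end-diastolic volume over the
    final ``n_beats`` beats (periodic steady-state diagnostic)."""
    period = ss.meta["period"]
    spb = int(round(period * ss.fs))
    v = ss.channels["V_LV"]
    edvs = []
    for k in range(n_beats + 1):
        seg = v[-(k + 1) * spb: v.size - k * spb if k else None]
        if seg.size:
            edvs.append(np.max(seg))
    edvs = np.array(edvs[::-1])
    return float(np.max(np.abs(np.diff(edvs)) / edvs[:-1]))


# ---------------------------------------------------------------------------
# Fick principle
# ---------------------------------------------------------------------------

def fick_svo2(cardiac_output: float, o2: O2Params) -> float:
    """Mixed venous saturation from the Fick principle (fraction).

    SvO2 = SaO2 - VO2 / (k_O2 * Hb * 10 * CO), clamped to [0, SaO2];
    CO in L/min, Hb in g/dL.
    """
    if cardiac_output <= 0:
        raise InvalidParameterError("cardiac output must be positive")
    svo2 = o2.sao2 - o2.vo2 / (o2.k_o2 * o2.hb * 10.0 * cardiac_output)
    return float(min(max(svo2, 0.0), o2.sao2))


# ---------------------------------------------------------------------------
# interventions
# ---------------------------------------------------------------------------

def apply_norepinephrine(model: AnimalModel, dose: float) -> AnimalModel:
    """Add ``dose`` ug/kg/min of norepinephrine to the infusion.

    Effects are applied multiplicatively at simulation time as
    (1+effect)**total_dose, so successive increments compose exactly and a
    zero increment returns a parameter-identical model.
    """
    if dose < 0:
        raise InvalidParameterError(f"dose must be >= 0, got {dose}")
    ne = model.ne.model_copy(update={"dose": model.ne.dose + dose})
    return model.copy_with(ne=ne)


def attach_impella(model: AnimalModel, pump: Optional[ImpellaParams] = None) -> AnimalModel:
    """Enable transvalvular pump support (defaults: device ceiling 3.5 L/min)."""
    pump = pump if pump is not None else model.pump
    pump = pump.model_copy(update={"enabled": True})
    return model.copy_with(pump=pump)


def _shock_step(model: AnimalModel, shock: ShockParams) -> AnimalModel:
    lv = model.lv.model_copy(update={"emax": model.lv.emax * (1.0 - shock.lv_emax_step)})
    rv = model.rv.model_copy(update={
        "emax": model.rv.emax * (1.0 - shock.rv_emax_step),
        "emin": model.rv.emin * (1.0 + shock.rv_emin_step),
    })
    circuit = model.circuit.model_copy(update={
        "r_pul_art": model.circuit.r_pul_art * (1.0 + shock.pvr_step),
        "total_volume": model.circuit.total_volume + shock.volume_per_injection,
    })
    return model.copy_with(lv=lv, rv=rv, circuit=circuit)


def add_volume(model: AnimalModel, volume: float) -> AnimalModel:
    """Account a net fluid gain (maintenance infusion over compressed
    protocol time) by raising total blood volume."""
    circuit = model.circuit.model_copy(
        update={"total_volume": model.circuit.total_volume + volume})
    return model.copy_with(circuit=circuit)


def induce_shock(
    model: AnimalModel,
    shock: Optional[ShockParams] = None,
    *,
    window: float = 12.0,
    settle: float = 20.0,
    y0: Optional[np.ndarray] = None,
    baseline: Optional[SignalSet] = None,
) -> Tuple[AnimalModel, int, dict]:
    """Stepwise microsphere shock until the profound-shock predicate holds.

    The predicate (evaluated on a re-simulated steady window after each
    injection): SvO2 <= drop_fraction * baseline SvO2, or SvO2 below the
    absolute floor, or sustained CO (mean over 10 beats) <= the ceiling.
    Returns (shocked model, number of injections, trajectory dict).
    """
    shock = shock if shock is not None else model.shock
    if baseline is None:
        baseline = simulate(model, window, settle=settle, y0=y0)
    co0 = baseline.meta["co"]
    svo2_0 = fick_svo2(co0, model.o2)
    y = baseline.extras["y_final"]
    traj = {"co": [co0], "svo2": [svo2_0], "lv_emax": [model.lv.emax]}
    m = model
    for k in range(1, shock.max_injections + 1):
        m = _shock_step(m, shock)
        y = y.copy()
        y[3] += shock.volume_per_injection  # crystalloid accrued over the interval
        ss = simulate(m, window, settle=0.0, y0=y)
        y = ss.extras["y_final"]
        co = ss.meta["co"]
        svo2 = fick_svo2(co, m.o2) if co > 0 else 0.0
        traj["co"].append(co)
        traj["svo2"].append(svo2)
        traj["lv_emax"].append(m.lv.emax)
        if (
            svo2 <= shock.svo2_drop_fraction * svo2_0
            or svo2 < shock.svo2_floor / 100.0
            or co <= shock.co_ceiling
        ):
            traj["y_final"] = y
            return m, k, traj
    raise ShockInductionFailure(
        f"stopping criteria not reached after {shock.max_injections} injections "
        f"(last CO {traj['co'][-1]:.2f} L/min, SvO2 {traj['svo2'][-1]:.2f})",
        trajectory=traj,
    )


# ---------------------------------------------------------------------------
# measurement manoeuvres
# ---------------------------------------------------------------------------

def ivc_occlusion_maneuver(
    model: AnimalModel,
    ramp_duration: float = 8.0,
    max_resistance_multiplier: float = 25.0,
    *,
    lead_in: float = 4.0,
    hold: float = 2.0,
    settle: float = 20.0,
    y0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> SignalSet:
    """Progressive inferior-vena-cava occlusion for ESPVR estimation.

    Venous-return resistance ramps linearly to ``max_resistance_multiplier``
    times its value over ``ramp_duration`` seconds after a steady lead-in.
    """
    period = 60.0 / effective_heart_rate(model)
    if ramp_duration < 5 * period:
        raise InsufficientBeatsError(
            f"ramp of {ramp_duration} s captures fewer than 5 beats at period {period:.2f} s"
        )
    duration = lead_in + ramp_duration + hold
    return simulate(
        model,
        duration,
        settle=settle,
        occlusion=(lead_in, ramp_duration, max_resistance_multiplier),
        y0=y0,
        rng=rng,
    )


def saline_bolus_maneuver(
    model: AnimalModel,
    bolus_duration: float = 9.0,
    conductivity_gain: float = 1.3,
    *,
    lead_in: float = 10.0,
    tail: float = 4.0,
    settle: float = 20.0,
    y0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> SignalSet:
    """Hypertonic-saline bolus: transient conductivity gain on the blood
    pool only (parallel component unscaled); true volumes are unchanged."""
    if conductivity_gain < 1.0:
        raise InvalidParameterError("conductivity_gain must be >= 1")
    duration = lead_in + bolus_duration + tail
    return simulate(
        model,
        duration,
        settle=settle,
        saline=(lead_in, bolus_duration, conductivity_gain),
        y0=y0,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _set_path(d: dict, path: str, value) -> None:
    keys = path.split(".")
    for k in keys[:-1]:
        d = d[k]
    d[keys[-1]] = value


def _get_path(d: dict, path: str):
    for k in path.split("."):
        d = d[k]
    return d


def sample_cohort(model: AnimalModel, n: int, seed: int) -> List[AnimalModel]:
    """Draw ``n`` animals around the nominal model.

    Each parameter listed in ``model.variability`` is multiplied by a
    lognormal factor with the configured coefficient of variation
    (median-preserving: factor = exp(sigma * Z), sigma^2 = ln(1 + CV^2)).
    Deterministic given ``seed``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cohort: List[AnimalModel] = []
    for i in range(n):
        ok = False
        for _ in range(100):
            d = model.to_dict()
            for path, cv in model.variability.items():
                if cv == 0:
                    continue
                sigma = math.sqrt(math.log(1.0 + cv * cv))
                factor = math.exp(sigma * rng.standard_normal())
                # "a+b" keys share one factor between both parameters
                for sub in path.split("+"):
                    _set_path(d, sub, _get_path(d, sub) * factor)
            d["seed"] = int(rng.integers(0, 2**31 - 1))
            try:
                cohort.append(AnimalModel.from_dict(d))
                ok = True
                break
            except (InvalidParameterError, ValueError):
                continue
        if not ok:
            raise CohortSamplingError(f"could not draw a valid animal #{i} in 100 attempts")
    return cohort
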