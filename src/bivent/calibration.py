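"""Conductance-catheter volume calibration.

The raw channel is a pseudo-volume G(t) = alpha * (V_blood(t) + Vp) plus
noise: a dimensionless gain ``alpha`` (segment geometry, field
inhomogeneity) and a parallel-conductance offset from the surrounding wall
and tissue, expressed as a volume equivalent ``Vp``.

``alpha`` is estimated by ratioing the uncalibrated stroke volume against
an independent reference stroke volume (thermodilution cardiac output over
heart rate).  ``Vp`` is estimated with the hypertonic-saline method: during
a transient rise of blood conductivity only the blood-pool component
scales, so per-beat (ED, ES) pseudo-volume pairs move along a line whose
intersection with the identity line ES = ED is the parallel component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import (
    CalibrationSanityError,
    DegenerateFitError,
    InsufficientBeatsError,
    InvalidParameterError,
)
from . import pv
from .signals import SignalSet


@dataclass
class SalineBeatSeries:
    """Per-beat uncalibrated ED/ES pseudo-volumes across a saline transient."""

    ed: np.ndarray
    es: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.ed = np.asarray(self.ed, dtype=float)
        self.es = np.asarray(self.es, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (self.ed.size == self.es.size == self.times.size):
            raise InvalidParameterError("ed/es/times must have equal length")
        if self.ed.size < 5:
            raise InsufficientBeatsError(
                f"saline series needs >= 5 beats, got {self.ed.size}"
            )
        if np.any(self.ed <= self.es):
            raise InvalidParameterError("each beat must have ED > ES pseudo-volume")


@dataclass
class CalibrationResult:
    """Gain and parallel-volume estimates with regression diagnostics.

    ``parallel_volume`` is in raw pseudo-volume units (the quantity
    subtracted from the raw channel); ``parallel_volume_ml`` is the same
    offset mapped through alpha into true millilitres.
    """

    alpha: float
    parallel_volume: float
    reference_sv: float
    slope: float = np.nan
    intercept: float = np.nan
    r2: float = np.nan
    n_beats: int = 0
    low_quality: bool = False

    @property
    def parallel_volume_ml(self) -> float:
        return self.parallel_volume / self.alpha

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "parallel_volume": self.parallel_volume,
            "parallel_volume_ml": self.parallel_volume_ml,
            "reference_sv": self.reference_sv,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n_beats": self.n_beats,
            "low_quality": self.low_quality,
        }


def estimate_alpha(uncal_sv: float, reference_sv: float) -> float:
    """Gain such that calibrated stroke volume matches the reference:
    alpha = uncalibrated SV / reference SV."""
    if uncal_sv <= 0 or reference_sv <= 0:
        raise InvalidParameterError(
            f"stroke volumes must be positive (got {uncal_sv}, {reference_sv})"
        )
    return float(uncal_sv / reference_sv)


def estimate_parallel_volume(
    series: SalineBeatSeries,
    r2_floor: float = 0.9,
    drift_correction: bool = False,
) -> Tuple[float, dict]:
    """Parallel pseudo-volume from the saline ES-on-ED regression.

    OLS of per-beat ES pseudo-volume on ED pseudo-volume; the parallel
    component is the intersection of the fitted line with the identity
    line V_es = V_ed.  With ``drift_correction`` a centred linear time
    covariate absorbs slow true-volume drift (e.g. the maintenance
    infusion) across the transient; the intersection is evaluated at the
    window midpoint.  Returns (Vp_pseudo, diagnostics).
    """
    if drift_correction:
        t = series.times - series.times.mean()
        X = np.column_stack([series.ed, t, np.ones_like(series.ed)])
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[-1] > 1e-8 * sv[0]:
            coef, *_ = np.linalg.lstsq(X, series.es, rcond=None)
            slope, icpt = float(coef[0]), float(coef[2])
            pred = X @ coef
        else:  # degenerate design (ED collinear with time): plain OLS
            slope, icpt = np.polyfit(series.ed, series.es, 1)
            pred = slope * series.ed + icpt
    else:
        slope, icpt = np.polyfit(series.ed, series.es, 1)
        pred = slope * series.ed + icpt
    if slope >= 1.0 - 1e-6:
        raise DegenerateFitError(
            f"ES-ED regression slope {slope:.6f} >= 1: no intersection with identity"
        )
    sst = float(np.sum((series.es - series.es.mean()) ** 2))
    r2 = 1.0 - float(np.sum((series.es - pred) ** 2)) / sst if sst > 0 else 1.0
    vp = float(icpt / (1.0 - slope))
    diag = {
        "slope": float(slope),
        "intercept": float(icpt),
        "r2": r2,
        "n_beats": int(series.ed.size),
        "low_quality": bool(r2 < r2_floor),
    }
    return vp, diag


def apply_calibration(raw_channel: np.ndarray, cal: CalibrationResult) -> np.ndarray:
    """Convert a raw pseudo-volume channel to millilitres:
    V(t) = raw(t)/alpha - Vp/alpha (identical convention for LV and RV)."""
    if cal.alpha <= 0:
        raise InvalidParameterError("alpha must be positive")
    v = (np.asarray(raw_channel, dtype=float) - cal.parallel_volume) / cal.alpha
    if not np.all(np.isfinite(v)):
        raise CalibrationSanityError("non-finite calibrated volumes")
    frac_neg = np.mean(v < -50.0)
    if frac_neg > 0.01:
        raise CalibrationSanityError(
            f"{100*frac_neg:.1f}% of calibrated samples below -50 mL"
        )
    return v


# ---------------------------------------------------------------------------
# high-level: calibrate a chamber from a saline-bolus recording
# ---------------------------------------------------------------------------

def smooth_volume(g: np.ndarray, fs: float) -> np.ndarray:
    """Light Savitzky-Golay denoising for conductance-derived volumes."""
    from scipy.signal import savgol_filter

    win = max(7, int(round(fs * 0.084)) | 1)
    if g.size <= win:
        return np.asarray(g, dtype=float)
    return savgol_filter(np.asarray(g, dtype=float), win, 3)


def _saline_phases(ss: SignalSet, pch: str, g: np.ndarray,
                   peaks: np.ndarray, before: float) -> Tuple[float, float]:
    """Median ED/ES phases (fractions of the peak-to-peak interval) from
    pre-bolus beats."""
    t_off = float(ss.time[0])
    ed_ph, es_ph = [], []
    for a, b in zip(peaks[:-1], peaks[1:]):
        if t_off + b / ss.fs >= before:
            continue
        if b - a < pv.MIN_BEAT_SAMPLES:
            continue
        beat = pv.Beat(p=ss.channels[pch][a:b], v=g[a:b], fs=ss.fs)
        f = pv.detect_fiducials(beat, v0_ref=0.0)
        ed_ph.append(f.ed_index / (b - a))
        es_ph.append(f.es_index / (b - a))
    if len(ed_ph) < 2:
        raise InsufficientBeatsError("too few pre-bolus beats to anchor ED/ES phases")
    return float(np.median(ed_ph)), float(np.median(es_ph))


def _refined_excursion(wave: np.ndarray) -> float:
    """Peak-to-peak range of a periodic waveform with the extremes refined
    by local quadratic fits (suppresses single-point noise bias)."""
    n = wave.size
    out = []
    for pick in (np.argmax, np.argmin):
        i = int(pick(wave))
        idx = (np.arange(i - 4, i + 5)) % n
        xx = np.arange(-4.0, 5.0)
        c = np.polyfit(xx, wave[idx], 2)
        if c[0] != 0:
            xv = np.clip(-c[1] / (2 * c[0]), -4.0, 4.0)
            out.append(np.polyval(c, xv))
        else:
            out.append(wave[i])
    return float(abs(out[0] - out[1]))


def _refined_peak_times(p: np.ndarray, fs: float, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample systolic peak times via parabolic interpolation."""
    t = peaks.astype(float)
    for k, i in enumerate(peaks):
        if 0 < i < p.size - 1:
            denom = p[i - 1] - 2.0 * p[i] + p[i + 1]
            if denom != 0.0:
                t[k] = i + 0.5 * (p[i - 1] - p[i + 1]) / denom
    return t / fs


def _phase_series(ss: SignalSet, g: np.ndarray, peak_times: np.ndarray,
                  window: Tuple[float, float],
                  ed_phase: float, es_phase: float) -> SalineBeatSeries:
    """Fixed-phase (ED, ES) pseudo-volume pairs across the transient.

    Beats are anchored on (sub-sample) pressure-peak times: pressure is
    unaffected by the bolus, so the anchors stay phase-stable while the
    conductance waveform is transiently rescaled.  Values are sampled at
    exact fractional phases of each peak-to-peak interval by interpolation,
    which keeps the underlying true volume exactly periodic even when the
    beat period is incommensurate with the sampling rate.  The ED paired
    with each ES is interpolated between the neighbouring end-diastoles at
    the ES time, compensating conductivity drift within the beat.
    """
    t_rel = ss.time - float(ss.time[0])
    ed_t, ed_v, es_t, es_v = [], [], [], []
    for a, b in zip(peak_times[:-1], peak_times[1:]):
        T = b - a
        te = a + ed_phase * T
        ts = a + es_phase * T
        ed_t.append(te)
        ed_v.append(float(np.interp(te, t_rel, g)))
        es_t.append(ts)
        es_v.append(float(np.interp(ts, t_rel, g)))
    ed_t = np.asarray(ed_t)
    ed_v = np.asarray(ed_v)
    ed, es, times = [], [], []
    for t, v in zip(es_t, es_v):
        if not (window[0] <= t <= window[1]):
            continue
        e = float(np.interp(t, ed_t, ed_v))
        if e > v:
            ed.append(e)
            es.append(v)
            times.append(t)
    return SalineBeatSeries(ed=np.array(ed), es=np.array(es), times=np.array(times))


def saline_series_from_signals(
    ss: SignalSet,
    chamber: str,
    window: Tuple[float, float],
    es_phase_offset: float = 0.0,
) -> SalineBeatSeries:
    """Per-beat (ED, ES) pseudo-volumes across the saline transient."""
    pch = "P_LV" if chamber.upper() == "LV" else "P_RV"
    gch = "G_LV" if chamber.upper() == "LV" else "G_RV"
    g = smooth_volume(ss.channels[gch], ss.fs)
    peaks = pv.pressure_peaks(ss.channels[pch], ss.fs)
    ed_phase, es_phase = _saline_phases(ss, pch, g, peaks, window[0])
    pt = _refined_peak_times(ss.channels[pch], ss.fs, peaks)
    return _phase_series(ss, g, pt, window, ed_phase, es_phase + es_phase_offset)


def calibrate_chamber(
    ss: SignalSet,
    chamber: str,
    saline_window: Tuple[float, float],
    reference_sv: float,
    steady_window: Optional[Tuple[float, float]] = None,
    n_steady_beats: int = 10,
    r2_floor: float = 0.9,
) -> CalibrationResult:
    """Full calibration of one chamber from a saline-bolus recording.

    Alpha from the mean uncalibrated SV over steady beats (before the
    bolus) against ``reference_sv``; Vp from the saline regression.
    """
    pch = "P_LV" if chamber.upper() == "LV" else "P_RV"
    gch = "G_LV" if chamber.upper() == "LV" else "G_RV"
    g = smooth_volume(ss.channels[gch], ss.fs)
    beats = pv.segment_beats(ss.channels[pch], g, ss.fs)
    t_off = float(ss.time[0])
    if steady_window is None:
        # steady beats must precede the bolus itself, not just the
        # regression window (which may start mid-transient)
        t_bolus = next((t for t, tag in ss.annotations if tag == "saline_bolus_start"),
                       saline_window[0])
        steady_window = (float(ss.time[0]), min(t_bolus, saline_window[0]))
    steady = [b for b in beats
              if steady_window[0] <= t_off + b.t0 + 0.5 * b.period <= steady_window[1]]
    if len(steady) < 3:
        raise InsufficientBeatsError(
            f"only {len(steady)} steady beats before the bolus for alpha estimation"
        )
    # excursion of the phase-resampled ensemble-average beat: averaging
    # across beats before taking extremes avoids the upward bias per-beat
    # peak-to-peak ranges acquire from sensor noise, and exact fractional-
    # phase resampling keeps beats aligned when the period is not an
    # integer number of samples
    pk = pv.pressure_peaks(ss.channels[pch], ss.fs)
    pt = _refined_peak_times(ss.channels[pch], ss.fs, pk)
    t_rel = ss.time - t_off
    phases = np.linspace(0.0, 1.0, 96, endpoint=False)
    waves = []
    for a, b in zip(pt[:-1], pt[1:]):
        if not (steady_window[0] <= b <= steady_window[1]):
            continue
        # raw channel: ensemble averaging handles the noise, and the
        # polynomial smoother's overshoot at the sharp end-diastolic corner
        # would bias the excursion
        waves.append(np.interp(a + phases * (b - a), t_rel, ss.channels[gch]))
    if len(waves) < 3:
        raise InsufficientBeatsError("too few steady intervals for alpha estimation")
    mean_beat = np.mean(waves[-n_steady_beats:], axis=0)
    uncal_sv = _refined_excursion(mean_beat)
    alpha = estimate_alpha(uncal_sv, reference_sv)
    # average the intersection over a few distinct sampling phases: each
    # phase pair defines a different line through the same parallel-
    # conductance point, so the estimates are nearly independent in noise
    ed_phase, es_phase = _saline_phases(ss, pch, g, pk, saline_window[0])
    vps, diag = [], None
    for off in (-0.12, -0.06, 0.0, 0.06, 0.12):
        series = _phase_series(ss, g, pt, saline_window,
                               ed_phase, es_phase + off)
        try:
            vp_k, diag_k = estimate_parallel_volume(series, r2_floor=r2_floor)
        except (DegenerateFitError, InsufficientBeatsError):
            continue
        vps.append(vp_k)
        if off == 0.0:
            diag = diag_k
    if not vps or diag is None:
        raise DegenerateFitError("no usable saline phase regression")
    vp = float(np.mean(vps))
    return CalibrationResult(
        alpha=alpha,
        parallel_volume=vp,
        reference_sv=reference_sv,
        slope=diag["slope"],
        intercept=diag["intercept"],
        r2=diag["r2"],
        n_beats=diag["n_beats"],
        low_quality=diag["low_quality"],
    )
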