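"""Pressure-volume loop analysis.

Segments beats, locates end-diastole (ED) and end-systole (ES), fits the
end-systolic pressure-volume relationship (ESPVR) from a preload-occlusion
beat family, and computes the derived indices: stroke work (SW), potential
energy (PE), pressure-volume area (PVA = SW + PE), effective arterial
elastance (Ea = ESP/SV), end-systolic elastance (Ees), the zero-pressure
volume intercept (Vo), and the ventriculo-arterial coupling ratio Ea/Ees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    DegenerateFitError,
    FiducialError,
    InsufficientBeatsError,
    InvalidBeatError,
    OpenLoopError,
    SegmentationError,
)

MIN_BEAT_SAMPLES = 20


@dataclass
class Beat:
    """P and V samples of one cardiac cycle of a single chamber."""

    p: np.ndarray
    v: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.p.size != self.v.size:
            raise InvalidBeatError("P and V must have equal length")
        if self.p.size < MIN_BEAT_SAMPLES:
            raise InvalidBeatError(
                f"beat has {self.p.size} samples, need >= {MIN_BEAT_SAMPLES}"
            )

    @property
    def period(self) -> float:
        return self.p.size / self.fs


@dataclass
class FiducialPoints:
    ed_index: int
    es_index: int
    ed_time: float
    es_time: float
    ed_pressure: float
    ed_volume: float
    es_pressure: float
    es_volume: float


@dataclass
class BeatIndices:
    """Per-beat derived quantities (volumes mL, pressures mmHg, work mmHg*mL)."""

    edv: float
    esv: float
    edp: float
    esp: float
    sv: float
    sw: float
    pe: float
    pva: float
    ea: float
    pva_hr: float  # PVA x HR, mmHg*mL/min

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ESPVRFit:
    ees: float
    vo: float
    es_points: np.ndarray  # (n_beats, 2): V_es, P_es
    r2: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# segmentation and fiducials
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    win = int(round(fs * 0.04))
    win = max(5, win | 1)  # odd, >= 5
    if x.size <= win:
        return x
    return savgol_filter(x, win, 3)


def pressure_peaks(p: np.ndarray, fs: float, max_heart_rate: float = 220.0) -> np.ndarray:
    """Systolic pressure-peak sample indices (beat anchors)."""
    p = np.asarray(p, dtype=float)
    prange = float(np.ptp(p))
    if prange < 1.0:
        raise SegmentationError("no cardiac periodicity detected (flat pressure)")
    ps = _smooth(p, fs)
    peaks, _ = find_peaks(ps, prominence=0.4 * prange, distance=int(fs * 60.0 / max_heart_rate))
    if peaks.size < 3:
        raise SegmentationError(f"only {peaks.size} systolic peaks found, need >= 3")
    return peaks


def segment_beats(
    p: np.ndarray,
    v: np.ndarray,
    fs: float,
    min_heart_rate: float = 30.0,
    max_heart_rate: float = 220.0,
) -> List[Beat]:
    """Split continuous P/V channels into beats delimited at end-diastole.

    Beat boundaries are the volume maxima just before each systolic pressure
    upstroke; partial first and last cycles are discarded.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.size != v.size:
        raise SegmentationError("P and V must have equal length")
    prange = float(np.ptp(p))
    if prange < 1.0:
        raise SegmentationError("no cardiac periodicity detected (flat pressure)")
    ps = _smooth(p, fs)
    vs = _smooth(v, fs)
    min_dist = int(fs * 60.0 / max_heart_rate)
    peaks, _ = find_peaks(ps, prominence=0.4 * prange, distance=min_dist)
    if peaks.size < 3:
        raise SegmentationError(f"only {peaks.size} systolic peaks found, need >= 3")
    ipis = np.diff(peaks)
    if np.median(ipis) > fs * 60.0 / min_heart_rate:
        raise SegmentationError("inter-peak interval implausibly long")
    # boundary: max volume between successive pressure peaks, biased to the
    # filled state just before the next upstroke
    bounds = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        lo = a + (b - a) // 3
        w = vs[lo:b]
        if w.size == 0:
            continue
        bounds.append(lo + int(np.argmax(w)))
    beats = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= MIN_BEAT_SAMPLES:
            beats.append(Beat(p=p[a:b], v=v[a:b], fs=fs, t0=a / fs))
    if not beats:
        raise SegmentationError("no complete beats between detected boundaries")
    return beats


def detect_fiducials(beat: Beat, v0_ref: float = 0.0) -> FiducialPoints:
    """Locate end-diastole and end-systole within one beat.

    ED: the maximal-volume sample in the low-pressure (pre-upstroke) state.
    ES: the sample maximising P/(V - v0_ref) over the pressurised part of
    the beat (ejection to early relaxation), the standard maximal-elastance
    criterion.  Both rules are invariant under circular shifts of the beat.
    """
    p, v = beat.p, beat.v
    if np.any(v <= v0_ref):
        raise FiducialError(
            f"volume reaches {v.min():.1f} mL <= v0_ref {v0_ref:.1f} mL; reference too large"
        )
    prange = np.ptp(p)
    vrange = np.ptp(v)
    if prange <= 0 or vrange <= 0:
        raise FiducialError("degenerate beat (flat P or V)")
    # ED: big volume, low pressure
    score = (v - v.min()) / vrange - 0.3 * (p - p.min()) / prange
    ed = int(np.argmax(score))
    # ES: max elastance among pressurised samples
    mask = p >= p.min() + 0.25 * prange
    ratio = np.where(mask, p / (v - v0_ref), -np.inf)
    es = int(np.argmax(ratio))
    n = p.size
    return FiducialPoints(
        ed_index=ed, es_index=es,
        ed_time=beat.t0 + ed / beat.fs, es_time=beat.t0 + es / beat.fs,
        ed_pressure=float(p[ed]), ed_volume=float(v[ed]),
        es_pressure=float(p[es]), es_volume=float(v[es]),
    )


# ---------------------------------------------------------------------------
# energetic indices
# ---------------------------------------------------------------------------

def stroke_work(beat: Beat, closure_tol: float = 0.15) -> float:
    """Loop area of the P-V trajectory (shoelace formula), mmHg*mL.

    Orientation-independent and non-negative.  Raises OpenLoopError if the
    trajectory's endpoints differ by more than ``closure_tol`` of the
    excursion in either coordinate.
    """
    p, v = beat.p, beat.v
    vrange, prange = np.ptp(v), np.ptp(p)
    if vrange > 0 and abs(v[0] - v[-1]) > closure_tol * vrange:
        raise OpenLoopError(f"volume endpoints differ by {abs(v[0]-v[-1]):.2f} mL")
    if prange > 0 and abs(p[0] - p[-1]) > closure_tol * prange:
        raise OpenLoopError(f"pressure endpoints differ by {abs(p[0]-p[-1]):.2f} mmHg")
    area = 0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p)
    return float(abs(area))


def potential_energy(esp: float, esv: float, vo: float) -> float:
    """Triangle approximation of end-systolic stored energy, mmHg*mL.

    PE = ESP * (ESV - Vo) / 2, floored at zero (with a warning) when the
    end-systolic volume falls below the ESPVR intercept.
    """
    if not (np.isfinite(esp) and np.isfinite(esv) and np.isfinite(vo)):
        raise InvalidBeatError("non-finite inputs to potential_energy")
    pe = esp * (esv - vo) / 2.0
    if pe < 0:
        warnings.warn("ESV below Vo; potential energy floored at 0", stacklevel=2)
        return 0.0
    return float(pe)


def arterial_elastance(esp: float, sv: float) -> float:
    """Effective arterial elastance Ea = ESP / SV, mmHg/mL."""
    if sv <= 0:
        raise InvalidBeatError(f"stroke volume must be positive, got {sv}")
    return float(esp / sv)


def coupling_ratio(ea: float, ees: float) -> float:
    """Ventriculo-arterial coupling reported as Ea/Ees (dimensionless)."""
    if ees <= 0:
        raise DegenerateFitError(f"Ees must be positive, got {ees}")
    return float(ea / ees)


# ---------------------------------------------------------------------------
# ESPVR fitting
# ---------------------------------------------------------------------------

def fit_espvr(
    beats: Sequence[Beat],
    tol: float = 0.01,
    max_iter: int = 50,
) -> ESPVRFit:
    """Iterative linear ESPVR fit on an occlusion beat family.

    Starting from Vo = 0: locate each beat's ES point as the maximum of
    P/(V - Vo), regress P_es on V_es by ordinary least squares, update Vo to
    the fitted volume intercept, and repeat until |dVo| < tol mL.  Ees is
    the converged slope.
    """
    if len(beats) < 5:
        raise InsufficientBeatsError(f"need >= 5 occlusion beats, got {len(beats)}")
    vo = 0.0
    slope = np.nan
    icpt = np.nan
    pts = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        es_v, es_p = [], []
        for b in beats:
            try:
                f = detect_fiducials(b, v0_ref=vo)
            except FiducialError:
                continue
            es_v.append(f.es_volume)
            es_p.append(f.es_pressure)
        if len(es_v) < 5:
            raise InsufficientBeatsError(
                f"only {len(es_v)} usable beats at Vo={vo:.1f} mL"
            )
        es_v = np.asarray(es_v)
        es_p = np.asarray(es_p)
        if np.ptp(es_v) < 1e-9:
            raise DegenerateFitError("end-systolic volumes are all equal")
        slope, icpt = np.polyfit(es_v, es_p, 1)
        if slope <= 0:
            raise DegenerateFitError(f"non-positive ESPVR slope {slope:.3f}")
        vo_new = -icpt / slope
        pts = np.column_stack([es_v, es_p])
        if abs(vo_new - vo) < tol:
            vo = vo_new
            converged = True
            break
        vo = vo_new
    resid = pts[:, 1] - (slope * pts[:, 0] + icpt)
    sst = np.sum((pts[:, 1] - pts[:, 1].mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / sst) if sst > 0 else 1.0
    return ESPVRFit(ees=float(slope), vo=float(vo), es_points=pts,
                    r2=r2, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def beat_indices(
    beat: Beat,
    fiducials: Optional[FiducialPoints] = None,
    espvr: Optional[ESPVRFit] = None,
    heart_rate: Optional[float] = None,
) -> BeatIndices:
    """Assemble all per-beat indices; PVA = SW + PE holds exactly."""
    vo = espvr.vo if espvr is not None else 0.0
    if fiducials is None:
        fiducials = detect_fiducials(beat, v0_ref=max(vo, 0.0) * 0.0)
    hr = heart_rate if heart_rate is not None else 60.0 / beat.period
    edv, esv = fiducials.ed_volume, fiducials.es_volume
    edp, esp = fiducials.ed_pressure, fiducials.es_pressure
    sv = edv - esv
    if sv <= 0:
        raise InvalidBeatError(f"non-ejecting beat (SV = {sv:.2f} mL)")
    sw = stroke_work(beat)
    pe = potential_energy(esp, esv, vo)
    pva = sw + pe
    return BeatIndices(
        edv=edv, esv=esv, edp=edp, esp=esp, sv=sv,
        sw=sw, pe=pe, pva=pva,
        ea=arterial_elastance(esp, sv),
        pva_hr=pva * hr,
    )
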