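"""Four-stage cardiogenic-shock protocol: orchestration, stage measurement,
cohort statistics and table building.

Stages per animal: baseline -> microsphere shock -> transvalvular pump +
minimum titrated norepinephrine (MAP threshold) -> norepinephrine
escalation (+0.10 ug/kg/min, a configurable subset of the cohort).  Each
stage is measured from a steady recording through the conductance-
calibration and PV-analysis pipeline; the end-systolic pressure-volume
relationship is fitted from a preload-occlusion run per stage, while the
zero-pressure intercept Vo used for potential energy is fitted once at
baseline and reused (the occlusion at baseline is the reference manoeuvre).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats as sps

from . import calibration as cal
from . import pv
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    TitrationFailure,
)
from .params import AnimalModel
from .sim import (
    add_volume,
    apply_norepinephrine,
    attach_impella,
    fick_svo2,
    induce_shock,
    ivc_occlusion_maneuver,
    mean_co,
    sample_cohort,
    saline_bolus_maneuver,
    simulate,
)
from .signals import SignalSet

STAGES = ("baseline", "shock", "impella_min_ne", "impella_mod_ne")


class ProtocolConfig(BaseModel):
    """Timing, manoeuvre and titration settings for one protocol run.

    Stage durations are compressed relative to the live experiment (the
    model has no slow dynamics); the net fluid balance of the compressed
    intervals is carried as discrete volume adjustments.
    """

    model_config = ConfigDict(extra="forbid")

    settle_duration: float = Field(default=22.0, gt=0, description="s")
    stage_duration: float = Field(default=12.0, gt=0, description="s")
    analysis_beats: int = Field(default=10, ge=3)
    occlusion_ramp: float = Field(default=8.0, gt=0, description="s")
    occlusion_multiplier: float = Field(default=25.0, gt=1)
    saline_duration: float = Field(default=9.0, gt=0, description="s")
    saline_gain: float = Field(default=1.3, gt=1)
    saline_lead_in: float = Field(default=10.0, gt=0, description="s")
    saline_repeats: int = Field(
        default=6, ge=1,
        description="number of bolus repetitions averaged per calibration")
    map_threshold: float = Field(default=45.0, gt=0, description="mmHg")
    dose_grid: List[float] = Field(
        default_factory=lambda: [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
    )
    escalation_dose: float = Field(default=0.10, ge=0)
    stage3_volume: float = Field(
        default=-250.0,
        description="net fluid balance entering the pump stage, mL",
    )
    stage4_volume: float = Field(
        default=101.0, description="net fluid balance entering the escalation stage, mL"
    )
    include_escalation: bool = Field(default=True)
    calibrate_per_stage: bool = Field(default=False)
    espvr_r2_warn: float = Field(default=0.9)

    @property
    def sorted_grid(self) -> List[float]:
        g = sorted(self.dose_grid)
        if not g or g[0] != 0.0:
            raise InvalidParameterError("dose grid must be ascending and include 0")
        return g


@dataclass
class ChamberStage:
    """Median per-beat indices of one chamber over the analysis window."""

    edv: float
    esv: float
    edp: float
    esp: float
    sv: float
    sw: float
    pe: float
    pva: float
    ea: float
    pva_hr: float
    ees: float = np.nan
    vo: float = np.nan
    ea_over_ees: float = np.nan


@dataclass
class StageRecord:
    stage: str
    ne_dose: float
    map: float
    hr: float
    co: float
    svo2: float  # percent
    pap_sys: float
    pap_dia: float
    pap_mean: float
    cvp: float
    lv: ChamberStage = None
    rv: ChamberStage = None
    ratios: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnimalRun:
    animal_index: int
    seed: int
    records: List[StageRecord]
    n_injections: int
    min_dose: float
    calibrations: Dict[str, dict]
    espvr: Dict[str, dict]

    def record(self, stage: str) -> Optional[StageRecord]:
        for r in self.records:
            if r.stage == stage:
                return r
        return None

    def as_dict(self) -> dict:
        return {
            "animal_index": self.animal_index,
            "seed": self.seed,
            "n_injections": self.n_injections,
            "min_dose": self.min_dose,
            "records": [r.as_dict() for r in self.records],
            "calibrations": self.calibrations,
            "espvr": self.espvr,
        }


# ---------------------------------------------------------------------------
# stage measurement
# ---------------------------------------------------------------------------

def _beat_stat(values: Sequence[float]) -> float:
    return float(np.median(values)) if len(values) else np.nan


def measure_stage(
    ss: SignalSet,
    model: AnimalModel,
    stage: str,
    cal_lv: cal.CalibrationResult,
    cal_rv: cal.CalibrationResult,
    espvr_lv: Optional[pv.ESPVRFit],
    espvr_rv: Optional[pv.ESPVRFit],
    ees: Optional[Dict[str, float]] = None,
    n_beats: int = 10,
) -> StageRecord:
    """Build a StageRecord from a steady recording.

    Volumes come from the calibrated conductance channels; cardiac output
    is the Swan-Ganz surrogate (true simulated pulmonary flow); SvO2 from
    the Fick relation.
    """
    co = mean_co(ss, n_beats)
    hr = ss.meta["heart_rate"]
    svo2 = fick_svo2(co, model.o2) * 100.0 if co > 0 else 0.0
    spb = int(round(ss.meta["period"] * ss.fs))
    win = slice(max(0, ss.time.size - n_beats * spb), None)
    pap = ss.channels["P_PA"][win]
    pap_sys, pap_dia = [], []
    for k in range(n_beats):
        seg = pap[k * spb:(k + 1) * spb]
        if seg.size:
            pap_sys.append(seg.max())
            pap_dia.append(seg.min())
    rec = StageRecord(
        stage=stage,
        ne_dose=model.ne.dose,
        map=float(np.mean(ss.channels["P_AO"][win])),
        hr=hr,
        co=co,
        svo2=svo2,
        pap_sys=_beat_stat(pap_sys),
        pap_dia=_beat_stat(pap_dia),
        pap_mean=float(np.mean(pap)),
        cvp=float(np.mean(ss.channels["P_CV"][win])),
    )
    for chamber, c, espvr in (("lv", cal_lv, espvr_lv), ("rv", cal_rv, espvr_rv)):
        pch = "P_LV" if chamber == "lv" else "P_RV"
        gch = "G_LV" if chamber == "lv" else "G_RV"
        v = cal.smooth_volume(cal.apply_calibration(ss.channels[gch], c), ss.fs)
        beats = pv.segment_beats(ss.channels[pch], v, ss.fs)
        use = beats[-n_beats:]
        idx = []
        for b in use:
            try:
                bi = pv.beat_indices(b, espvr=espvr, heart_rate=hr)
            except Exception:
                continue
            idx.append(bi)
        if not idx:
            raise InsufficientDataError(f"no usable beats for {chamber} at stage {stage}")
        med = {k: _beat_stat([getattr(i, k) for i in idx]) for k in
               ("edv", "esv", "edp", "esp", "sv", "sw", "pe", "pva", "ea", "pva_hr")}
        ch = ChamberStage(**med)
        ch.vo = espvr.vo if espvr is not None else np.nan
        if ees is not None and chamber in ees:
            ch.ees = ees[chamber]
            ch.ea_over_ees = pv.coupling_ratio(ch.ea, ch.ees)
        rec.__dict__[chamber] = ch
    rec.ratios = {
        "edv": rec.rv.edv / rec.lv.edv,
        "edp": rec.rv.edp / rec.lv.edp if rec.lv.edp else np.nan,
        "sw": rec.rv.sw / rec.lv.sw,
        "pva_hr": rec.rv.pva_hr / rec.lv.pva_hr,
    }
    return rec


def _fit_stage_espvr(
    model: AnimalModel,
    y0: np.ndarray,
    cfg: ProtocolConfig,
    cal_lv: cal.CalibrationResult,
    cal_rv: cal.CalibrationResult,
    rng: np.random.Generator,
) -> Tuple[pv.ESPVRFit, pv.ESPVRFit, SignalSet]:
    """Run an IVC occlusion from the given state and fit both ESPVRs on the
    calibrated conductance volumes."""
    ss = ivc_occlusion_maneuver(
        model,
        ramp_duration=cfg.occlusion_ramp,
        max_resistance_multiplier=cfg.occlusion_multiplier,
        settle=0.0,
        y0=y0,
        rng=rng,
    )
    t_start = next(t for t, tag in ss.annotations if tag == "occlusion_start")
    fits = {}
    for chamber, c in (("lv", cal_lv), ("rv", cal_rv)):
        pch = "P_LV" if chamber == "lv" else "P_RV"
        gch = "G_LV" if chamber == "lv" else "G_RV"
        v = cal.smooth_volume(cal.apply_calibration(ss.channels[gch], c), ss.fs)
        beats = pv.segment_beats(ss.channels[pch], v, ss.fs)
        occ = [b for b in beats if b.t0 + ss.time[0] >= t_start - 0.2]
        # keep the monotone-preload-reduction family
        fam = []
        prev = np.inf
        for b in occ:
            edv = b.v.max()
            if edv < prev:
                fam.append(b)
                prev = edv
        fits[chamber] = pv.fit_espvr(fam)
    return fits["lv"], fits["rv"], ss


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

def titrate_min_ne(
    model: AnimalModel,
    map_threshold: float = 45.0,
    dose_grid: Optional[Sequence[float]] = None,
    *,
    y0: Optional[np.ndarray] = None,
    window: float = 10.0,
    settle: float = 6.0,
) -> float:
    """Smallest grid dose whose steady-state MAP reaches the threshold.

    Returns 0.0 if the pump alone is sufficient; raises TitrationFailure
    (with the best achieved MAP) if no grid dose suffices.
    """
    grid = sorted(dose_grid) if dose_grid is not None else [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
    if not grid or grid[0] != 0.0:
        raise InvalidParameterError("dose grid must be ascending and include 0")
    best_map = -np.inf
    for dose in grid:
        md = apply_norepinephrine(model, dose)
        ss = simulate(md, window, settle=settle, y0=y0)
        best_map = max(best_map, ss.meta["map"])
        if ss.meta["map"] >= map_threshold:
            return float(dose)
    raise TitrationFailure(
        f"no dose on the grid reaches MAP {map_threshold} mmHg "
        f"(best {best_map:.1f})",
        achieved_map=best_map,
    )


# ---------------------------------------------------------------------------
# per-animal protocol
# ---------------------------------------------------------------------------

def run_animal_protocol(
    model: AnimalModel,
    cfg: Optional[ProtocolConfig] = None,
    seed: Optional[int] = None,
    *,
    animal_index: int = 0,
    escalate: bool = True,
) -> AnimalRun:
    """Execute the full four-stage protocol on one animal.

    Deterministic given (model, cfg, seed): all measurement noise is drawn
    from a single generator seeded with ``seed`` (default: the model seed).
    """
    cfg = cfg or ProtocolConfig()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    records: List[StageRecord] = []

    # --- baseline: settle, saline calibration, occlusion, stage window
    base_ss = simulate(model, cfg.stage_duration, settle=cfg.settle_duration, rng=rng)
    y = base_ss.extras["y_final"]
    # regress on the washout side of the transient (the fast wash-in phase
    # has high curvature between beats); boluses are repeated and the
    # estimates averaged, as is standard practice
    win = (cfg.saline_lead_in + cfg.saline_duration / 3.0 + 0.8,
           cfg.saline_lead_in + cfg.saline_duration + 6.0)
    cals = {"lv": [], "rv": []}
    for _ in range(cfg.saline_repeats):
        sal = saline_bolus_maneuver(
            model,
            bolus_duration=cfg.saline_duration,
            conductivity_gain=cfg.saline_gain,
            lead_in=cfg.saline_lead_in,
            tail=6.0,
            settle=0.0,
            y0=y,
            rng=rng,
        )
        y = sal.extras["y_final"]
        # reference SV from the same pre-bolus steady window as the
        # uncalibrated excursion (thermodilution surrogate); the first
        # beats after the warm start are excluded
        steady = (max(0.0, cfg.saline_lead_in - 6.0), cfg.saline_lead_in)
        ref_sv = mean_co(sal, window=steady) * 1000.0 / sal.meta["heart_rate"]
        cals["lv"].append(cal.calibrate_chamber(sal, "LV", win, ref_sv,
                                                steady_window=steady))
        cals["rv"].append(cal.calibrate_chamber(sal, "RV", win, ref_sv,
                                                steady_window=steady))
    cal_lv = _average_calibrations(cals["lv"])
    cal_rv = _average_calibrations(cals["rv"])
    espvr_lv, espvr_rv, _ = _fit_stage_espvr(model, y, cfg, cal_lv, cal_rv, rng)
    records.append(measure_stage(
        base_ss, model, "baseline", cal_lv, cal_rv, espvr_lv, espvr_rv,
        ees={"lv": espvr_lv.ees, "rv": espvr_rv.ees}, n_beats=cfg.analysis_beats,
    ))

    # --- shock induction
    m_shock, n_inj, traj = induce_shock(model, baseline=base_ss)
    y = traj["y_final"]
    ss = simulate(m_shock, cfg.stage_duration, settle=6.0, y0=y, rng=rng)
    y = ss.extras["y_final"]
    fit_lv_s, fit_rv_s, _ = _fit_stage_espvr(m_shock, y, cfg, cal_lv, cal_rv, rng)
    records.append(measure_stage(
        ss, m_shock, "shock", cal_lv, cal_rv, espvr_lv, espvr_rv,
        ees={"lv": fit_lv_s.ees, "rv": fit_rv_s.ees}, n_beats=cfg.analysis_beats,
    ))

    # --- pump + minimum norepinephrine
    m_imp = attach_impella(m_shock)
    m_imp = add_volume(m_imp, cfg.stage3_volume)
    y = y.copy()
    y[3] += cfg.stage3_volume
    ss_ia = simulate(m_imp, cfg.stage_duration, settle=6.0, y0=y, rng=rng)
    y = ss_ia.extras["y_final"]
    min_dose = titrate_min_ne(
        m_imp, cfg.map_threshold, cfg.sorted_grid, y0=y,
    )
    m3 = apply_norepinephrine(m_imp, min_dose)
    ss = simulate(m3, cfg.stage_duration, settle=10.0, y0=y, rng=rng)
    y = ss.extras["y_final"]
    fit_lv_3, fit_rv_3, _ = _fit_stage_espvr(m3, y, cfg, cal_lv, cal_rv, rng)
    records.append(measure_stage(
        ss, m3, "impella_min_ne", cal_lv, cal_rv, espvr_lv, espvr_rv,
        ees={"lv": fit_lv_3.ees, "rv": fit_rv_3.ees}, n_beats=cfg.analysis_beats,
    ))

    # --- escalation (+0.10 ug/kg/min) in the configured subset
    espvr_meta = {
        "lv_baseline": _fit_meta(espvr_lv), "rv_baseline": _fit_meta(espvr_rv),
        "lv_shock": _fit_meta(fit_lv_s), "rv_shock": _fit_meta(fit_rv_s),
        "lv_impella_min_ne": _fit_meta(fit_lv_3), "rv_impella_min_ne": _fit_meta(fit_rv_3),
    }
    if escalate and cfg.include_escalation:
        m4 = apply_norepinephrine(m3, cfg.escalation_dose)
        m4 = add_volume(m4, cfg.stage4_volume)
        y = y.copy()
        y[3] += cfg.stage4_volume
        ss = simulate(m4, cfg.stage_duration, settle=10.0, y0=y, rng=rng)
        y4 = ss.extras["y_final"]
        fit_lv_4, fit_rv_4, _ = _fit_stage_espvr(m4, y4, cfg, cal_lv, cal_rv, rng)
        records.append(measure_stage(
            ss, m4, "impella_mod_ne", cal_lv, cal_rv, espvr_lv, espvr_rv,
            ees={"lv": fit_lv_4.ees, "rv": fit_rv_4.ees}, n_beats=cfg.analysis_beats,
        ))
        espvr_meta["lv_impella_mod_ne"] = _fit_meta(fit_lv_4)
        espvr_meta["rv_impella_mod_ne"] = _fit_meta(fit_rv_4)

    _check_stage_invariants(records)
    return AnimalRun(
        animal_index=animal_index,
        seed=int(model.seed if seed is None else seed),
        records=records,
        n_injections=n_inj,
        min_dose=min_dose,
        calibrations={"lv": cal_lv.as_dict(), "rv": cal_rv.as_dict()},
        espvr=espvr_meta,
    )


def _average_calibrations(cs):
    import numpy as _np

    first = cs[0]
    return cal.CalibrationResult(
        alpha=float(_np.mean([c.alpha for c in cs])),
        parallel_volume=float(_np.mean([c.parallel_volume for c in cs])),
        reference_sv=float(_np.mean([c.reference_sv for c in cs])),
        slope=first.slope, intercept=first.intercept,
        r2=float(_np.mean([c.r2 for c in cs])),
        n_beats=int(sum(c.n_beats for c in cs)),
        low_quality=any(c.low_quality for c in cs),
    )


def _fit_meta(f: pv.ESPVRFit) -> dict:
    return {"ees": f.ees, "vo": f.vo, "r2": f.r2,
            "iterations": f.iterations, "converged": f.converged}


def _check_stage_invariants(records: List[StageRecord]) -> None:
    order = {s: i for i, s in enumerate(STAGES)}
    idx = [order[r.stage] for r in records]
    if idx != sorted(idx):
        raise InvalidParameterError("stage records out of protocol order")
    doses = [r.ne_dose for r in records]
    if any(b < a - 1e-12 for a, b in zip(doses, doses[1:])):
        raise InvalidParameterError("norepinephrine dose must be non-decreasing")


def run_cohort(
    model: AnimalModel,
    n: int = 18,
    escalation_n: int = 8,
    seed: int = 1,
    cfg: Optional[ProtocolConfig] = None,
) -> List[AnimalRun]:
    """Sample a cohort and run the protocol on each animal.

    The escalation subset is the first ``escalation_n`` animals of the
    seeded cohort (deterministic selection).
    """
    cohort = sample_cohort(model, n, seed)
    runs = []
    for i, animal in enumerate(cohort):
        runs.append(run_animal_protocol(
            animal, cfg, animal_index=i, escalate=(i < escalation_n),
        ))
    return runs


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class Summary:
    style: str  # "mean_sd" or "median_q"
    n: int
    center: float
    spread: Tuple[float, float]  # (sd, sd) or (q1, q3)

    def format(self, nd: int = 1) -> str:
        if self.style == "mean_sd":
            return f"{self.center:.{nd}f} ({self.spread[0]:.{nd}f})"
        return f"{self.center:.{nd}f} ({self.spread[0]:.{nd}f}, {self.spread[1]:.{nd}f})"


def summarize(values: Sequence[float], style: str = "auto") -> Summary:
    """Cohort summary: mean(SD) for normal-looking data, median(Q1, Q3)
    otherwise (Shapiro-Wilk at alpha = 0.05 decides in 'auto' mode)."""
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 values, got {x.size}")
    if style == "auto":
        if np.ptp(x) < 1e-12:
            style = "mean_sd"
        else:
            _, p = sps.shapiro(x)
            style = "mean_sd" if p >= 0.05 else "median_q"
    if style == "mean_sd":
        return Summary("mean_sd", x.size, float(np.mean(x)),
                       (float(np.std(x, ddof=1)), float(np.std(x, ddof=1))))
    if style == "median_q":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return Summary("median_q", x.size, float(med), (float(q1), float(q3)))
    raise InvalidParameterError(f"unknown summary style {style!r}")


@dataclass
class ComparisonResult:
    variable: str
    pair: Tuple[str, str]
    test: str  # "paired-t" or "signed-rank"
    statistic: float
    p_raw: float
    p_adjusted: float
    m: int
    n: int


def paired_compare(
    a: Sequence[float],
    b: Sequence[float],
    m: int = 1,
    variable: str = "",
    pair: Tuple[str, str] = ("a", "b"),
    test: str = "auto",
) -> ComparisonResult:
    """Paired comparison with Bonferroni adjustment over ``m`` comparisons.

    Differences passing a Shapiro-Wilk normality check (alpha 0.05) get a
    paired t-test; otherwise a Wilcoxon signed-rank test (exact null
    distribution for n <= 25, normal approximation with continuity
    correction above).  All-zero differences give a degenerate result with
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise InvalidParameterError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 5:
        raise InsufficientDataError(f"need >= 5 pairs, got {a.size}")
    d = b - a
    if np.all(d == 0):
        return ComparisonResult(variable, pair, "degenerate", 0.0, 1.0, 1.0, m, a.size)
    if test == "auto":
        _, p_norm = sps.shapiro(d)
        test = "paired-t" if p_norm >= 0.05 else "signed-rank"
    if test == "paired-t":
        t, p_raw = sps.ttest_rel(b, a)
        test, statn = "paired-t", float(t)
    else:
        method = "exact" if a.size <= 25 and not np.any(d == 0) else "approx"
        res = sps.wilcoxon(b, a, zero_method="wilcox", correction=(method == "approx"),
                           method=method)
        test, statn, p_raw = "signed-rank", float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        variable, pair, test, statn, float(p_raw),
        float(min(1.0, m * p_raw)), m, a.size,
    )


# ---------------------------------------------------------------------------
# report builder
# ---------------------------------------------------------------------------

def _get(rec: StageRecord, path: str) -> float:
    obj = rec
    for part in path.split("."):
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return float(obj)


# (row label, attribute path) per table, mirroring the printed row sets
TABLE1_ROWS = [
    ("NE dose, ug/kg/min", "ne_dose"),
    ("SvO2, %", "svo2"),
    ("Cardiac output, L/min", "co"),
    ("MAP, mmHg", "map"),
    ("Heart rate, bpm", "hr"),
    ("PAP systolic, mmHg", "pap_sys"),
    ("PAP diastolic, mmHg", "pap_dia"),
    ("PAP mean, mmHg", "pap_mean"),
    ("CVP, mmHg", "cvp"),
]
TABLE2_ROWS = [
    ("RV EDV, mL", "rv.edv"),
    ("RV ESP, mmHg", "rv.esp"),
    ("RV EDP, mmHg", "rv.edp"),
    ("RV Ees, mmHg/mL", "rv.ees"),
    ("RV Ea, mmHg/mL", "rv.ea"),
    ("RV Ea/Ees ratio", "rv.ea_over_ees"),
    ("LV EDV, mL", "lv.edv"),
    ("LV ESP, mmHg", "lv.esp"),
    ("LV EDP, mmHg", "lv.edp"),
    ("LV Ees, mmHg/mL", "lv.ees"),
    ("LV Ea, mmHg/mL", "lv.ea"),
    ("LV Ea/Ees", "lv.ea_over_ees"),
]
TABLE3_ROWS = [
    ("RV SW, mmHg x mL", "rv.sw"),
    ("RV PE, mmHg x mL", "rv.pe"),
    ("RV PVA x HR, mmHg x mL/min", "rv.pva_hr"),
    ("LV SW, mmHg x mL", "lv.sw"),
    ("LV PE, mmHg x mL", "lv.pe"),
    ("LV PVA x HR, mmHg x mL/min", "lv.pva_hr"),
    ("RV/LV PVA x HR ratio", "ratios.pva_hr"),
    ("RV/LV ratio of SW", "ratios.sw"),
]
TABLE5_ROWS = [
    ("RV EDV, mL", "rv.edv"),
    ("RV ESP, mmHg", "rv.esp"),
    ("RV EDP, mmHg", "rv.edp"),
    ("RV Ees, mmHg/mL", "rv.ees"),
    ("RV Ea, mmHg/mL", "rv.ea"),
    ("RV Ea/Ees ratio", "rv.ea_over_ees"),
    ("LV EDV, mL", "lv.edv"),
    ("LV ESP, mmHg", "lv.esp"),
    ("LV EDP, mmHg", "lv.edp"),
    ("RV/LV EDV ratio", "ratios.edv"),
    ("RV/LV EDP ratio", "ratios.edp"),
    ("LV Ees, mmHg/mL", "lv.ees"),
    ("LV Ea, mmHg/mL", "lv.ea"),
    ("LV Ea/Ees", "lv.ea_over_ees"),
    ("RV SW, mmHg x mL", "rv.sw"),
    ("RV PE, mmHg x mL", "rv.pe"),
    ("RV PVA x HR, mmHg x mL/min", "rv.pva_hr"),
    ("LV SW, mmHg x mL", "lv.sw"),
    ("LV PE, mmHg x mL", "lv.pe"),
    ("LV PVA x HR, mmHg x mL/min", "lv.pva_hr"),
]


@dataclass
class CohortTable:
    name: str
    stages: List[str]
    data: pd.DataFrame  # summary strings per (row, stage) + p-value columns
    comparisons: List[ComparisonResult]
    n_per_stage: Dict[str, int]

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    def to_markdown(self) -> str:
        header = f"### {self.name} (" + ", ".join(
            f"{s}: n={n}" for s, n in self.n_per_stage.items()) + ")\n\n"
        return header + self.data.to_markdown()


def _build_table(
    name: str,
    rows: List[Tuple[str, str]],
    runs: List[AnimalRun],
    stages: List[str],
    pairs: List[Tuple[str, str]],
) -> CohortTable:
    cols: Dict[str, list] = {}
    comparisons: List[ComparisonResult] = []
    n_per_stage = {}
    values: Dict[Tuple[str, str], np.ndarray] = {}
    for stage in stages:
        per_stage = []
        for label, path in rows:
            vals = []
            for run in runs:
                rec = run.record(stage)
                if rec is not None:
                    try:
                        vals.append(_get(rec, path))
                    except (AttributeError, KeyError):
                        vals.append(np.nan)
            values[(stage, label)] = np.asarray(vals, dtype=float)
        n_per_stage[stage] = int(sum(run.record(stage) is not None for run in runs))
    m = len(pairs)
    table_rows = {}
    for label, path in rows:
        row = {}
        for stage in stages:
            v = values[(stage, label)]
            v = v[np.isfinite(v)]
            row[stage] = summarize(v).format(2 if np.nanmax(np.abs(v), initial=0) < 20 else 1) if v.size >= 2 else "n/a"
        for pa, pb in pairs:
            va, vb = [], []
            for run in runs:
                ra, rb = run.record(pa), run.record(pb)
                if ra is not None and rb is not None:
                    try:
                        va.append(_get(ra, path))
                        vb.append(_get(rb, path))
                    except (AttributeError, KeyError):
                        pass
            key = f"p: {pa} vs {pb}"
            try:
                cr = paired_compare(va, vb, m=m, variable=label, pair=(pa, pb))
                comparisons.append(cr)
                row[key] = f"{cr.p_adjusted:.3g}"
            except (InsufficientDataError, InvalidParameterError):
                row[key] = "n/a"
        table_rows[label] = row
    df = pd.DataFrame.from_dict(table_rows, orient="index")
    return CohortTable(name=name, stages=stages, data=df,
                       comparisons=comparisons, n_per_stage=n_per_stage)


def build_report(runs: List[AnimalRun]) -> Dict[str, object]:
    """Five cohort tables plus the per-animal RV/LV EDV-ratio chart data.

    Tables 1-3: all animals over baseline / shock / pump + min NE with the
    two pairwise stage comparisons.  Tables 4-5: the escalation subset,
    pump + min NE vs + 0.10 ug/kg/min.
    """
    if len(runs) < 5:
        raise InsufficientDataError(f"need >= 5 completed animals, got {len(runs)}")
    first3 = ["baseline", "shock", "impella_min_ne"]
    pairs3 = [("baseline", "shock"), ("shock", "impella_min_ne")]
    esc = [r for r in runs if r.record("impella_mod_ne") is not None]
    last2 = ["impella_min_ne", "impella_mod_ne"]
    pairs2 = [("impella_min_ne", "impella_mod_ne")]
    report = {
        "table1": _build_table("Haemodynamics", TABLE1_ROWS, runs, first3, pairs3),
        "table2": _build_table("Pressure-volume indices", TABLE2_ROWS, runs, first3, pairs3),
        "table3": _build_table("Cardiac work", TABLE3_ROWS, runs, first3, pairs3),
        "table4": _build_table("Haemodynamics, escalation subset", TABLE1_ROWS, esc, last2, pairs2),
        "table5": _build_table("Pressure-volume and work, escalation subset", TABLE5_ROWS, esc, last2, pairs2),
    }
    # Fig-2-style chart data: per-animal EDV ratio at the first three stages
    ratio = {
        stage: [r.record(stage).ratios["edv"] for r in runs if r.record(stage)]
        for stage in first3
    }
    report["edv_ratio"] = pd.DataFrame(ratio)
    return report


def save_report(report: Dict[str, object], outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    md = []
    for key, tab in report.items():
        if isinstance(tab, CohortTable):
            tab.to_csv(outdir / f"{key}.csv")
            md.append(tab.to_markdown())
    report["edv_ratio"].to_csv(outdir / "edv_ratio.csv", index=False)
    (outdir / "report.md").write_text("\n\n".join(md) + "\n")
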