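"""Parameter containers for the virtual-animal circulation model.

All pressures are in mmHg, volumes in mL, times in s, resistances in
mmHg*s/mL, compliances in mL/mmHg, flows in mL/s unless stated otherwise.
The default values parameterise the *nominal* virtual animal: a ~70-75 kg
pig at anaesthetised baseline with a cardiac output near 5.5 L/min, mean
arterial pressure ~70 mmHg and biventricular elastances in the range
reported for this preparation (LV end-systolic elastance ~0.85 mmHg/mL,
RV ~0.30 mmHg/mL).
"""

from __future__ import annotations

from typing import Dict

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidParameterError


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ChamberParams(_Params):
    """Time-varying elastance chamber.

    P(t) = [emin + (emax - emin) * a(t)] * (V - v0) + P_pericardium, where
    a(t) is a double-Hill activation waveform normalised to peak exactly 1.
    ``act_tau1``/``act_tau2`` are expressed as fractions of the beat period
    so systolic timing scales with heart rate.
    """

    emax: float = Field(gt=0.0, description="end-systolic elastance, mmHg/mL")
    emin: float = Field(gt=0.0, description="diastolic elastance, mmHg/mL")
    v0: float = Field(ge=0.0, description="zero-pressure volume, mL")
    act_tau1: float = Field(default=0.269, gt=0.0, description="rise time constant, fraction of period")
    act_tau2: float = Field(default=0.452, gt=0.0, description="decay time constant, fraction of period")
    act_n1: float = Field(default=1.32, gt=0.0, description="rise shape exponent")
    act_n2: float = Field(default=21.9, gt=0.0, description="decay shape exponent")

    @model_validator(mode="after")
    def _check(self):
        if not self.emax > self.emin:
            raise InvalidParameterError(f"emax ({self.emax}) must exceed emin ({self.emin})")
        return self


class CircuitParams(_Params):
    """Lumped systemic and pulmonary vascular circuit."""

    r_av: float = Field(default=0.008, gt=0.0, description="aortic valve resistance")
    r_sys_art: float = Field(default=0.612, gt=0.0, description="systemic arterial resistance")
    r_sys_ven: float = Field(default=0.008, gt=0.0, description="systemic venous (return) resistance")
    r_tv: float = Field(default=0.002, gt=0.0, description="tricuspid valve resistance")
    r_pv: float = Field(default=0.006, gt=0.0, description="pulmonary valve resistance")
    r_pul_art: float = Field(default=0.0602, gt=0.0, description="pulmonary arterial resistance")
    r_pul_ven: float = Field(default=0.009, gt=0.0, description="pulmonary venous resistance")
    r_mv: float = Field(default=0.006, gt=0.0, description="mitral valve resistance")
    c_sys_art: float = Field(default=1.3, gt=0.0, description="systemic arterial compliance")
    c_sys_ven: float = Field(default=107.0, gt=0.0, description="systemic venous compliance")
    c_pul_art: float = Field(default=2.7, gt=0.0, description="pulmonary arterial compliance")
    c_pul_ven: float = Field(default=14.0, gt=0.0, description="pulmonary venous compliance")
    total_volume: float = Field(default=4439.0, gt=0.0, description="total blood volume, mL")
    vu_sys_art: float = Field(default=450.0, ge=0.0, description="unstressed systemic arterial volume")
    vu_sys_ven: float = Field(default=2150.0, ge=0.0, description="unstressed systemic venous volume")
    vu_pul_art: float = Field(default=80.0, ge=0.0, description="unstressed pulmonary arterial volume")
    vu_pul_ven: float = Field(default=250.0, ge=0.0, description="unstressed pulmonary venous volume")
    infusion_rate: float = Field(default=1000.0, ge=0.0, description="maintenance crystalloid, mL/h")

    @property
    def unstressed_total(self) -> float:
        return self.vu_sys_art + self.vu_sys_ven + self.vu_pul_art + self.vu_pul_ven

    @model_validator(mode="after")
    def _check(self):
        if not self.total_volume > self.unstressed_total:
            raise InvalidParameterError(
                "total stressed volume must be positive: total_volume "
                f"{self.total_volume} <= unstressed sum {self.unstressed_total}"
            )
        return self


class PericardiumParams(_Params):
    """Shared pericardial pressure, exponential in total heart volume.

    P_peri = gain * exp(steepness * (V_lv + V_rv - v_ref)); strictly
    positive and strictly increasing in total heart volume, which is what
    couples the two ventricles (interdependence within the pericardial
    constraint).
    """

    gain: float = Field(default=2.0, gt=0.0, description="mmHg")
    steepness: float = Field(default=0.011, gt=0.0, description="1/mL")
    v_ref: float = Field(default=315.0, ge=0.0, description="reference total heart volume, mL")


class ImpellaParams(_Params):
    """Transvalvular axial pump, linear head curve with soft suction clamp."""

    max_flow: float = Field(default=3.5, gt=0.0, le=3.5, description="flow at zero head, L/min")
    head_slope: float = Field(default=0.1, ge=0.0, description="flow lost per mmHg head, mL/s/mmHg")
    suction_volume: float = Field(default=40.0, ge=0.0, description="LV volume where down-regulation starts, mL")
    suction_width: float = Field(default=5.0, gt=0.0, description="smoothness of the suction ramp, mL")
    enabled: bool = Field(default=False)


class NEParams(_Params):
    """Phenomenological steady-state norepinephrine response.

    A baseline parameter is scaled multiplicatively by
    ``1 + eff * d / (d + d50)`` at total dose ``d`` (ug/kg/min): a
    saturating Emax-type dose-response with half-maximal dose ``d50``.
    ``eff`` is the maximal fractional effect.  The scaling is a function of
    the accumulated dose only, so successive dose increments compose
    exactly and dose 0 reproduces baseline bit-for-bit.
    """

    eff_lv_emax: float = Field(default=2.65)
    eff_rv_emax: float = Field(default=0.55)
    eff_hr: float = Field(default=0.185)
    eff_svr: float = Field(default=0.064)
    eff_pvr: float = Field(default=0.506)
    eff_venous_unstressed: float = Field(default=-0.155, gt=-1.0)
    d50: float = Field(default=0.089, gt=0.0, description="half-maximal dose, ug/kg/min")
    dose: float = Field(default=0.0, ge=0.0, description="ug/kg/min")


class ShockParams(_Params):
    """Stepwise coronary microsphere injections and stopping rule.

    Each injection multiplies LV emax by (1 - lv_emax_step) and RV emax by
    (1 - rv_emax_step); injections stop when mixed venous saturation has
    fallen to <= svo2_drop_fraction of baseline, or below svo2_floor
    absolute, or sustained cardiac output <= co_ceiling.
    """

    lv_emax_step: float = Field(default=0.111, ge=0.0, lt=1.0)
    rv_emax_step: float = Field(default=0.013, ge=0.0, lt=1.0)
    rv_emin_step: float = Field(
        default=0.056, ge=0.0, lt=1.0,
        description="fractional RV diastolic-elastance increase per injection "
        "(ischaemic diastolic stiffening)",
    )
    pvr_step: float = Field(
        default=0.102, ge=0.0, lt=1.0,
        description="fractional pulmonary-arterial resistance increase per injection "
        "(hypoxic pulmonary vasoconstriction accompanying the microsphere load)",
    )
    volume_per_injection: float = Field(
        default=27.0, ge=0.0,
        description="net fluid gain per injection interval, mL (maintenance crystalloid "
        "running over the real induction timeline, compressed here)",
    )
    max_injections: int = Field(default=15, ge=1)
    svo2_drop_fraction: float = Field(default=0.5, gt=0.0, lt=1.0)
    svo2_floor: float = Field(default=30.0, gt=0.0, description="absolute SvO2 floor, %")
    co_ceiling: float = Field(default=2.0, gt=0.0, description="L/min")


class O2Params(_Params):
    """Fick-principle oxygen transport for the mixed venous saturation."""

    vo2: float = Field(default=232.0, gt=0.0, description="O2 consumption, mL O2/min")
    hb: float = Field(default=10.0, gt=0.0, description="haemoglobin, g/dL")
    sao2: float = Field(default=0.98, gt=0.0, le=1.0, description="arterial saturation, fraction")
    k_o2: float = Field(default=1.34, gt=0.0, description="O2 capacity, mL O2/g Hb")


class ConductanceSensorParams(_Params):
    """Conductance-catheter volume channel: G = alpha*(V_blood + Vp) + noise.

    ``alpha`` is the dimensionless gain, ``parallel_volume`` the
    volume-equivalent of parallel (wall/tissue) conductance in mL, noise is
    additive Gaussian with SD ``noise_sd`` mL (volume-equivalent, applied
    in pseudo-volume units).  The segment constant rho*L^2 is lumped into
    the units so the raw channel reads in pseudo-mL.
    """

    alpha: float = Field(default=1.25, gt=0.0)
    parallel_volume: float = Field(default=50.0, ge=0.0, description="mL")
    noise_sd: float = Field(default=2.0, ge=0.0, description="mL")
    segment_constant: float = Field(default=1.0, gt=0.0)


_DEFAULT_VARIABILITY: Dict[str, float] = {
    # a "a+b" key draws one lognormal factor and applies it to both
    # parameters: global myocardial properties co-vary between ventricles,
    # which keeps the interventricular balance physiological
    "lv.emax+rv.emax": 0.10,
    "lv.emax": 0.04,
    "rv.emax": 0.04,
    "lv.emin+rv.emin": 0.06,
    "lv.emin": 0.02,
    "rv.emin": 0.02,
    "circuit.r_sys_art": 0.10,
    "circuit.r_pul_art": 0.08,
    "circuit.c_sys_art": 0.08,
    "circuit.total_volume": 0.03,
    "o2.vo2": 0.06,
    "heart_rate": 0.05,
    "pericardium.gain": 0.08,
}


class AnimalModel(_Params):
    """Complete parameterisation of one virtual animal."""

    lv: ChamberParams = Field(default_factory=lambda: ChamberParams(emax=0.85, emin=0.046, v0=13.0))
    rv: ChamberParams = Field(default_factory=lambda: ChamberParams(emax=0.26, emin=0.034, v0=10.0))
    circuit: CircuitParams = Field(default_factory=CircuitParams)
    pericardium: PericardiumParams = Field(default_factory=PericardiumParams)
    pump: ImpellaParams = Field(default_factory=ImpellaParams)
    ne: NEParams = Field(default_factory=NEParams)
    shock: ShockParams = Field(default_factory=ShockParams)
    o2: O2Params = Field(default_factory=O2Params)
    lv_sensor: ConductanceSensorParams = Field(
        default_factory=lambda: ConductanceSensorParams(alpha=1.25, parallel_volume=50.0)
    )
    rv_sensor: ConductanceSensorParams = Field(
        default_factory=lambda: ConductanceSensorParams(alpha=1.1, parallel_volume=60.0)
    )
    heart_rate: float = Field(default=82.0, gt=0.0, description="bpm")
    variability: Dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_VARIABILITY))
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        for key, cv in self.variability.items():
            if cv < 0:
                raise InvalidParameterError(f"variability CV for {key!r} must be >= 0, got {cv}")
        return self

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return self.model_dump()

    @classmethod
    def from_dict(cls, d: dict) -> "AnimalModel":
        return cls.model_validate(d)

    def copy_with(self, **updates) -> "AnimalModel":
        return self.model_copy(update=updates, deep=True)


def nominal_animal(seed: int = 0) -> AnimalModel:
    """The packaged nominal virtual animal (all defaults)."""
    return AnimalModel(seed=seed)
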