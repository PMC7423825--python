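"""Shared fixtures: expensive simulator runs are session-scoped."""

import numpy as np
import pytest

from bivent import AnimalModel, nominal_animal
from bivent.sim import induce_shock, ivc_occlusion_maneuver, simulate


@pytest.fixture(scope="session")
def nominal():
    return nominal_animal()


@pytest.fixture(scope="session")
def quiet_model(nominal):
    """Nominal animal with noiseless conductance sensors."""
    d = nominal.to_dict()
    d["lv_sensor"]["noise_sd"] = 0.0
    d["rv_sensor"]["noise_sd"] = 0.0
    return AnimalModel.from_dict(d)


@pytest.fixture(scope="session")
def baseline_ss(nominal):
    """Steady baseline recording of the nominal animal."""
    return simulate(nominal, 12.0, settle=22.0)


@pytest.fixture(scope="session")
def quiet_baseline_ss(quiet_model):
    return simulate(quiet_model, 12.0, settle=22.0)


@pytest.fixture(scope="session")
def shocked(nominal, baseline_ss):
    """(shocked model, n_injections, trajectory) for the nominal animal."""
    return induce_shock(nominal, baseline=baseline_ss)


@pytest.fixture(scope="session")
def quiet_occlusion(quiet_model, quiet_baseline_ss):
    """Noise-free IVC occlusion run from the baseline steady state."""
    return ivc_occlusion_maneuver(
        quiet_model, settle=0.0, y0=quiet_baseline_ss.extras["y_final"]
    )


@pytest.fixture(scope="session")
def animal_run(nominal):
    """Full four-stage protocol on the nominal animal (takes a few s)."""
    from bivent.protocol import run_animal_protocol

    return run_animal_protocol(nominal)


def occlusion_beat_family(ss, chamber="LV", calibrated=None):
    """Monotone-EDV beat family from an occlusion recording.

    Uses the true volume channel unless a calibrated channel is given.
    """
    from bivent import pv

    pch = "P_LV" if chamber == "LV" else "P_RV"
    vch = "V_LV" if chamber == "LV" else "V_RV"
    v = calibrated if calibrated is not None else ss.channels[vch]
    t0 = next(t for t, tag in ss.annotations if tag == "occlusion_start")
    beats = pv.segment_beats(ss.channels[pch], v, ss.fs)
    fam, prev = [], np.inf
    for b in beats:
        if b.t0 >= t0 - 0.2 and b.v.max() < prev:
            fam.append(b)
            prev = b.v.max()
    return fam
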