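import numpy as np
import pytest

from neckconnective import ephys, synth
from neckconnective.probes import RecordingConfig, make_probe


def simulate_and_estimate(v_true, seed=3, duration_s=8.0, noise_sd=1.0,
                          amplitude_sd=5.0, rate_hz=13.0):
    """Simulate one propagating unit and run the full velocity chain."""
    geom = make_probe()
    cfg = RecordingConfig(duration_s=duration_s, noise_sd=noise_sd, seed=seed)
    unit = synth.UnitSpec(velocity_mps=v_true, amplitude_sd=amplitude_sd,
                          rate_hz=rate_hz)
    rec = synth.simulate_recording(geom, [unit], cfg)
    spikes = {0: np.round(rec.spike_times_s[0] * cfg.fs_hz).astype(int)}
    est = ephys.measure_unit_velocities(rec.as_float(), cfg.fs_hz, spikes, geom)[0]
    return rec, est


@pytest.fixture(scope="session")
def est_2mps():
    """Velocity estimate for a simulated 2 m/s ascending unit (~100 spikes)."""
    _, est = simulate_and_estimate(2.0)
    return est


@pytest.fixture(scope="session")
def est_2mps_reversed():
    _, est = simulate_and_estimate(-2.0)
    return est
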