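import numpy as np
import pandas as pd
import pytest

from atsea import association_core as ac
from atsea import synthetic_data as sd
from atsea import track_preprocess as tp


@pytest.fixture(scope="session")
def small_study():
    """A seeded, noiseless 10-bird / 2-day study with its preprocessing.

    Shared read-only across tests; session-scoped because simulation plus
    preprocessing takes a couple of seconds.
    """
    cfg = sd.SimConfig(
        seed=11,
        colony=sd.ColonyConfig(n_birds=10),
        stage_schedule=((1, "guard"), (1, "post-guard")),
        sensor=sd.SensorConfig(gps_noise_m=0.0, dropout_prob=0.0),
    )
    deployments, gps, tdr, truth, truth_windows = sd.simulate_study(cfg)
    trips, tracks, dives = tp.preprocess_study(gps, tdr, deployments)
    events = ac.detect_all_associations(tracks)
    return {
        "config": cfg,
        "deployments": deployments,
        "gps": gps,
        "tdr": tdr,
        "truth": truth,
        "truth_windows": truth_windows,
        "trips": trips,
        "tracks": tracks,
        "dives": dives,
        "events": events,
    }


def make_track(bird_id, t, lat, lon, phase=tp.PHASE_FORAGING, trip_index=0):
    """Assemble a shared-grid track table for detector tests."""
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "trip_index": trip_index,
            "t": np.asarray(t, dtype=np.int64),
            "lat": lat,
            "lon": lon,
            "depth": 0.0,
            "phase": phase,
        }
    )


@pytest.fixture
def track_factory():
    return make_track
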