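import numpy as np
import pandas as pd
import pytest

import stalltrack as st


@pytest.fixture(scope="session")
def small_scenario():
    """A 6000-frame default scenario (50 min at 2 images/s), seed 1."""
    return st.build_scenario({"n_frames": 6000, "seed": 1})


@pytest.fixture(scope="session")
def small_run(small_scenario):
    """Simulated truth + labels + degraded tracks + artifact log."""
    truth, labels = st.simulate_tracks(small_scenario)
    tracks, log = st.degrade_to_predictions(
        truth, small_scenario.artifacts, seed=2, geometry=small_scenario.geometry
    )
    return {
        "scenario": small_scenario,
        "truth": truth,
        "labels": labels,
        "tracks": tracks,
        "log": log,
    }


def make_track(marker="nose", frames=None, x=None, y=None, predicted=None):
    frames = np.asarray(frames if frames is not None else [1, 2, 3])
    n = len(frames)
    x = np.asarray(x if x is not None else np.full(n, 100.0), dtype=float)
    y = np.asarray(y if y is not None else np.full(n, 200.0), dtype=float)
    predicted = np.asarray(
        predicted if predicted is not None else np.ones(n, dtype=bool)
    )
    return st.MarkerTrack(marker=marker, frames=frames, x=x, y=y, predicted=predicted)


def make_truth(rows):
    """rows: iterable of (frame, marker, x, y, visibility); x/y may be None."""
    return st.GroundTruthTable(
        pd.DataFrame(rows, columns=["frame", "marker", "x", "y", "visibility"])
    )
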