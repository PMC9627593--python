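import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import filatwist as ft


def random_pair_frame(rng: np.random.Generator) -> ft.PairFrame:
    """A uniformly random right-handed pair triad (d1 = d3 x d2)."""
    m = Rotation.random(random_state=rng).as_matrix()
    d3, d2 = m[:, 2], m[:, 1]
    return ft.PairFrame(
        origin=rng.normal(0, 10, 3), d1=np.cross(d3, d2), d2=d2, d3=d3
    )


def rotate_frame_about_d3(frame: ft.PairFrame, angle_deg: float) -> ft.PairFrame:
    rot = Rotation.from_rotvec(np.radians(angle_deg) * frame.d3)
    d2 = rot.apply(frame.d2)
    return ft.PairFrame(
        origin=frame.origin, d1=np.cross(frame.d3, d2), d2=d2, d3=frame.d3
    )


@pytest.fixture(scope="session")
def paper_modes_catalog():
    """Segmented catalog of the documented 20 x 2000-frame ensemble."""
    traces = ft.paper_modes_ensemble(
        n_traces=20, n_frames=2000, noise_sigma=1.2, base_seed=1
    )
    segments = {
        f"ensemble-{i:02d}": ft.detect_states(trace)
        for i, trace in enumerate(traces)
    }
    return ft.StateCatalog.from_segments(segments)
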