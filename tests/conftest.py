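import numpy as np
import pytest

import neurofrac as nf


@pytest.fixture(scope="session")
def small_fixture_set():
    """Named binary fixtures at most 64x64, for exhaustive/oracle tests."""
    return {
        "filled_16": nf.make_filled_rect(16, 16),
        "filled_5x9": nf.make_filled_rect(9, 5),
        "line_h64": nf.make_line(64, "horizontal"),
        "line_v32": nf.make_line(32, "vertical"),
        "line_d32": nf.make_line(32, "diagonal"),
        "sierpinski_5": nf.make_sierpinski(5),
        "disk_20": nf.make_disk(20),
        "tree_64_a": nf.make_random_neuron(
            nf.TreeParams(seed=11, canvas_px=64, segment_len_px=7.0, max_depth=5)
        ),
        "tree_64_b": nf.make_random_neuron(
            nf.TreeParams(seed=12, canvas_px=64, segment_len_px=7.0, max_depth=5,
                          thickness_px=3)
        ),
        "offcenter_blob": nf.BinaryImage(_blob_mask()),
    }


def _blob_mask():
    m = np.zeros((40, 64), dtype=bool)
    m[3:9, 50:61] = True
    m[20:23, 5:35] = True
    m[30, 40] = True
    return m


@pytest.fixture(scope="session")
def tree_fixture_set():
    """Random trees at analysis scale, the stand-ins for neuron drawings."""
    params = nf.TreeParams(canvas_px=512)
    out = {}
    for seed in (3, 7, 21):
        out[f"tree_{seed}"] = nf.make_random_neuron(
            nf.TreeParams(**{**params.__dict__, "seed": seed})
        )
    out["tree_thick"] = nf.make_random_neuron(
        nf.TreeParams(seed=5, canvas_px=512, thickness_px=3)
    )
    return out
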