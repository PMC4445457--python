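import numpy as np
import pandas as pd
import pytest

from pulsecraft import (
    CellTrack,
    EmbryoDataset,
    SynthConfig,
    align_embryo,
    generate_embryo,
)


def make_track(cell_id, times, myosin, area, neighbors=(), is_boundary=False,
               embryo_id="e1", centroid=(0.0, 0.0)):
    n = len(times)
    return CellTrack(
        cell_id=cell_id,
        embryo_id=embryo_id,
        times=np.asarray(times, float),
        myosin=np.asarray(myosin, float),
        area=np.asarray(area, float),
        centroid=np.tile(centroid, (n, 1)),
        neighbors=list(neighbors),
        is_boundary=is_boundary,
    )


@pytest.fixture
def tiny_dataset():
    """Three mutually adjacent cells, ten frames, one missing observation."""
    times = np.arange(0.0, 60.0, 6.0)
    myo = 5.0 + 0.1 * times
    area = 40.0 - 0.05 * times
    myo_b = myo.copy()
    myo_b[4] = np.nan  # a missing frame, preserved through I/O
    cells = {
        "a": make_track("a", times, myo, area, ["b", "c"], centroid=(0, 0)),
        "b": make_track("b", times, myo_b, area + 1, ["a", "c"], centroid=(7, 0)),
        "c": make_track("c", times, myo, area + 2, ["a", "b"], centroid=(3.5, 6),
                        is_boundary=True),
    }
    return EmbryoDataset(embryo_id="e1", cells=cells, genotype="wild_type")


@pytest.fixture(scope="session")
def research_embryo():
    """A wild-type-programme embryo at analysis scale, aligned to t = 0."""
    cfg = SynthConfig(rows=10, cols=10, duration=600.0)
    dataset, truth = generate_embryo(cfg, seed=5)
    align_embryo(dataset, mode="area_threshold")
    aligned = dataset.apply_alignment()
    pulses = truth.pulses.copy()
    pulses["embryo_id"] = "synthetic"
    return aligned, pulses, truth


@pytest.fixture(scope="session")
def coupled_embryo():
    """Embryo with ratcheted-only neighbour coupling (enrichment construction)."""
    cfg = SynthConfig(rows=14, cols=14, duration=500.0, coupling={"ratcheted": 0.5})
    dataset, truth = generate_embryo(cfg, seed=7)
    aligned = dataset.apply_alignment(truth.t_zero_raw)
    pulses = truth.pulses.copy()
    pulses["embryo_id"] = "synthetic"
    return aligned, pulses, truth
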