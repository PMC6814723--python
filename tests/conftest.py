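from __future__ import annotations

import numpy as np
import pytest

from clonoscope import (
    AnalysisConfig,
    CellRecord,
    Clone,
    ColorDisplay,
    GenerationConfig,
    generate_dataset,
    run_pipeline,
)

RARE = ColorDisplay(frozenset({"C", "Y"}), frozenset({"R"}))


def make_cell(
    cid,
    x=0.0,
    y=0.0,
    z=0.0,
    display=RARE,
    animal="A01",
    stage="P7",
    subtype="PrA",
    edu=None,
):
    return CellRecord(
        cell_id=str(cid),
        x=x,
        y=y,
        z=z,
        display=display,
        animal_id=animal,
        stage=stage,
        subtype=subtype,
        edu_positive=edu,
    )


def make_clone(points, clone_id="cl0", subtype="PrA", **kw):
    cells = [
        make_cell(f"{clone_id}_{i}", *map(float, p), subtype=subtype, **kw)
        for i, p in enumerate(points)
    ]
    return Clone(
        clone_id=clone_id,
        cells=cells,
        display=RARE,
        animal_id=cells[0].animal_id,
        stage=cells[0].stage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dataset200():
    """Default synthetic slab: 200 clones, fixed seed, with ground truth."""
    return generate_dataset(GenerationConfig(), seed=0)


@pytest.fixture(scope="session")
def report200(dataset200):
    """Pipeline report for the default synthetic slab."""
    return run_pipeline(None, cells=dataset200.cells, config=AnalysisConfig())
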