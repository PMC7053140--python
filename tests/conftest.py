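import numpy as np
import pytest

from cellpile import GenomicRegion
from cellpile.simulate import ScenarioSpec, make_scenario


@pytest.fixture
def region():
    return GenomicRegion("chr1", 10_000, 20_000)


@pytest.fixture
def small_region():
    return GenomicRegion("chr1", 0, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def bimodal_scenario(tmp_path):
    spec = ScenarioSpec(
        kind="bimodal_expression", n_cells=8, seed=11,
        groups=[("0h", 4), ("12h", 4)], depth=120,
    )
    return make_scenario(spec, str(tmp_path / "bimodal"))


def scenario_sources(result):
    """(cell_id, path, 'bam') triples plus group labels from a scenario."""
    truth = result.ground_truth
    sources = [
        (cid, path, "bam")
        for cid, path in zip(truth.cell_id, result.bam_paths)
    ]
    return sources, list(truth.group)
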