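import pytest

from urimine.datasets import load_marker_table, load_subnetwork_scores
from urimine.pipeline import PipelineConfig
from urimine.simulate import SynthConfig, write_bundle


@pytest.fixture(scope="session")
def marker_fixture():
    """The packaged 19-row candidate urinary-marker table."""
    return load_marker_table()


@pytest.fixture(scope="session")
def subnetwork_scores():
    """The packaged published (BC, CC) pairs for the 10 subnetwork hubs."""
    return load_subnetwork_scores()


@pytest.fixture()
def synth_bundle(tmp_path):
    """A default-condition synthetic bundle on disk plus its truth."""
    config = SynthConfig(seed=11)
    truth = write_bundle(config, tmp_path / "bundle")
    pipeline_config = PipelineConfig.from_yaml(tmp_path / "bundle" / "pipeline.yaml")
    return config, truth, pipeline_config
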