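import json
import time
from pathlib import Path

import pytest

from convmine.demo import write_demo_inputs
from convmine.pipeline import PipelineConfig, run_pipeline
from convmine.signature_io import SignatureSet


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Generate the synthetic demo inputs, run the full pipeline once, and
    expose (directory, manifest, planted-structure ledger, wall time)."""
    directory = tmp_path_factory.mktemp("demo")
    start = time.monotonic()
    config_path = write_demo_inputs(directory, seed=7)
    manifest = run_pipeline(PipelineConfig.from_yaml(config_path))
    elapsed = time.monotonic() - start
    ledger = json.loads((directory / "ledger.json").read_text())
    return {
        "dir": Path(directory),
        "manifest": manifest,
        "ledger": ledger,
        "elapsed": elapsed,
    }


@pytest.fixture()
def tiny_sigs() -> SignatureSet:
    """Hand-checkable two-category collection."""
    return SignatureSet(
        name="tiny", categories={"A": ["P", "Q"], "B": ["Q"]}, provenance="test"
    )
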