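import json
from pathlib import Path

import pytest

from druggenome import pipeline, synth


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> tuple[dict, dict, Path]:
    """Default synthetic bundle: (paths, manifest, directory)."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths, manifest = synth.generate(synth.SyntheticConfig(seed=17), outdir)
    return paths, manifest, outdir


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> tuple[dict, dict, Path]:
    """Full pipeline run on the default synthetic profile: (summary, manifest, outdir)."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = pipeline.RunConfig(synthetic=True, seed=17, outdir=str(outdir))
    summary = pipeline.run_all(cfg)
    manifest = json.loads((outdir / "inputs" / "manifest.json").read_text())
    return summary, manifest, outdir
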