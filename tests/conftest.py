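import pytest

from mmavirome import pipeline as pl
from mmavirome import synthetic as syn
from mmavirome.records import Config


@pytest.fixture(scope="session")
def default_cfg() -> Config:
    return Config(rng_seed=42)


@pytest.fixture(scope="session")
def community() -> syn.CommunityBundle:
    """The default synthetic community at seed 42, shared across tests."""
    return syn.generate_community(syn.GeneratorParams(rng_seed=42))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, community, default_cfg):
    """One full pipeline run on the default community: (input_dir, output_dir, manifest)."""
    root = tmp_path_factory.mktemp("pipeline")
    indir, outdir = root / "in", root / "out"
    syn.write_bundle(community, indir)
    manifest = pl.run_pipeline(default_cfg, indir, outdir)
    return indir, outdir, manifest
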