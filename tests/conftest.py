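import pytest

from cypfam import synth


@pytest.fixture(scope="session")
def default_dataset():
    """One standard six-species synthetic complement, shared across tests."""
    return synth.generate(synth.default_config(seed=42))


@pytest.fixture(scope="session")
def dataset_bundle(default_dataset, tmp_path_factory):
    """The default dataset written out as FASTA/GFF3/names/truth files."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = default_dataset.write(outdir)
    return default_dataset, paths
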