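import json
from pathlib import Path

import pytest

from hmmasm.cli import RunConfig, run_all
from hmmasm.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("fix_clean")
    manifest = make_fixture("clean", root)
    return root, manifest


@pytest.fixture(scope="session")
def two_haplotype_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("fix_2hap")
    manifest = make_fixture("two_haplotype", root)
    return root, manifest


@pytest.fixture(scope="session")
def shared_kmer_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("fix_shared")
    manifest = make_fixture("shared_kmer", root)
    return root, manifest


@pytest.fixture(scope="session")
def low_coverage_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("fix_low")
    manifest = make_fixture("low_coverage", root)
    return root, manifest


def clean_config(root: Path, out: Path, **kw) -> RunConfig:
    genes = {g: str(root / g) for g in ("nirk", "rplb")}
    return RunConfig(reads=str(root / "reads.fastq"), genes=genes, out=str(out), k=45, **kw)


@pytest.fixture(scope="session")
def clean_run(clean_fixture, tmp_path_factory):
    """One full workflow execution on the clean community, shared by tests."""
    root, manifest = clean_fixture
    out = tmp_path_factory.mktemp("clean_out")
    result = run_all(clean_config(root, out))
    return root, manifest, result, out
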