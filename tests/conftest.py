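import logging

import pysam
import pytest

from clipfuse.pipeline import RunConfig, run_pipeline
from clipfuse.simulate import write_fixture_set

logging.getLogger("clipfuse").setLevel(logging.ERROR)

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Full synthetic bundle: genome, gene models, planted-fusion BAM, truth."""
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixture_set(out, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def models(fixture_set):
    return fixture_set["models"]


@pytest.fixture(scope="session")
def genome(fixture_set):
    return fixture_set["genome"]


@pytest.fixture(scope="session")
def bam(fixture_set):
    return pysam.AlignmentFile(str(fixture_set["bam"]))


def make_config(fixture_set, out_dir, **kw) -> RunConfig:
    return RunConfig(
        bam=str(fixture_set["bam"]),
        reference=str(fixture_set["fasta"]),
        refflat=str(fixture_set["refflat"]),
        proteins=str(fixture_set["proteins"]),
        known_fusions=str(fixture_set["known_fusions"]),
        itd_genes=str(fixture_set["itd_genes"]),
        blacklist=str(fixture_set["blacklist"]),
        fusion_blacklist=str(fixture_set["fusion_blacklist"]),
        out_dir=str(out_dir),
        **kw,
    )


@pytest.fixture(scope="session")
def pipeline_result(fixture_set, tmp_path_factory):
    """One default-mode pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("pipe_out")
    return run_pipeline(make_config(fixture_set, out))
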