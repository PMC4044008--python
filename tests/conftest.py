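import sys
from pathlib import Path

import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncscreen import DatasetSpec, PipelineConfig, generate_dataset, run_pipeline

DATASET_SEED = 1


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """The default synthetic dataset, generated once per session."""
    outdir = tmp_path_factory.mktemp("synthetic")
    return generate_dataset(DATASET_SEED, outdir, DatasetSpec())


@pytest.fixture(scope="session")
def pipeline_result(dataset, tmp_path_factory):
    """One full cascade run over the session dataset."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        transcripts_fasta=str(dataset.transcripts_fasta),
        transcripts_gff3=str(dataset.transcripts_gff3),
        genes_gff3=str(dataset.genes_gff3),
        counts_tsv=str(dataset.counts_tsv),
        precursors_fasta=str(dataset.precursors_fasta),
        shrna_fasta=str(dataset.shrna_fasta),
        sirna_fasta=str(dataset.sirna_fasta),
        cds_fasta=str(dataset.cds_fasta),
        tissue_tsv=str(dataset.tissue_tsv),
        outdir=str(outdir),
    )
    return run_pipeline(cfg)
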