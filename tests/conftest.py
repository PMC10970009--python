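import numpy as np
import pytest

from tfmeta import SynthConfig, generate_dataset

# small but complete multiome: enough plants per motif to score recovery,
# small enough that every module test stays fast
TINY = dict(
    n_cell_types=4,
    cells_per_type=20,
    n_motifs=20,
    n_peaks_per_class={"prom": 40, "enhD": 40, "exon": 8, "none": 4},
    plants_per_class={"prom": 2, "enhD": 2},
)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_multiome")
    cfg = SynthConfig(seed=42, **TINY)
    gt = generate_dataset(cfg, out)
    return cfg, gt, out


@pytest.fixture(scope="session")
def tiny_genome(tiny_dataset):
    from Bio import SeqIO
    _, _, out = tiny_dataset
    return {r.id: str(r.seq) for r in SeqIO.parse(str(out / "genome.fa"), "fasta")}


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """Full study conditions: 8 cell types x 200 cells, 200 motifs."""
    out = tmp_path_factory.mktemp("study_multiome")
    cfg = SynthConfig(seed=11)
    gt = generate_dataset(cfg, out)
    return cfg, gt, out


@pytest.fixture(scope="session")
def study_pipeline(study_dataset, tmp_path_factory):
    """One full pipeline run on the study-scale dataset."""
    from tfmeta import run_all, synthetic_config

    _, gt, data_dir = study_dataset
    out = tmp_path_factory.mktemp("study_out")
    cfg = synthetic_config(data_dir, out, enrichment_seed=7)
    run_all(cfg)
    return cfg, gt, out
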