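import numpy as np
import pytest

from gliascan import annotate, genomes, seq_core, synthetic


@pytest.fixture
def motif_table():
    return genomes.load_motif_table()


@pytest.fixture
def seg_cfg():
    return annotate.SegmentationConfig()


@pytest.fixture
def small_cohort():
    cfg = synthetic.GeneratorConfig(seed=42, n_accessions=2, n_seqs_per_accession=25)
    records, truth = synthetic.generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture
def write_tmp_fasta(tmp_path):
    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def plan_protein(genome, seed=0, **cfg_kwargs):
    """A single noise-free template protein with its construction plan."""
    cfg = synthetic.GeneratorConfig(seed=seed, **cfg_kwargs)
    rng_ = np.random.default_rng(seed)
    plan = synthetic._build_plan(genome, cfg, rng_)
    return plan


@pytest.fixture
def canonical_d_plan():
    return plan_protein("D", seed=3)


@pytest.fixture
def record_factory():
    def _make(seq, rid="r1", label=""):
        return seq_core.NucleotideRecord(id=rid, seq=seq, accession_label=label)

    return _make
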