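import pytest

from hairpinforge.folding import MaxPairEngine
from hairpinforge.preprocess import RawRead, clean_reads, collapse
from hairpinforge.synthetic_data import SimConfig, generate_transcriptome, simulate_reads


@pytest.fixture(scope="session")
def engine():
    """Session-scoped bundled folding engine (amortizes JIT warm-up)."""
    eng = MaxPairEngine()
    eng.fold("GCGCGCAAAAGCGCGC")  # warm the kernel
    return eng


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with every structural feature planted."""
    config = SimConfig(
        seed=11,
        n_transcripts=40,
        n_planted_mirnas=10,
        n_decoys=8,
        n_clusters=1,
        n_multi_mature=1,
        n_antisense=1,
        depth_min=5,
        read_error_rate=0.0,
        jitter_prob=0.0,
    )
    transcripts, truth = generate_transcriptome(config)
    reads = simulate_reads(truth, config)
    return config, transcripts, truth, reads


@pytest.fixture(scope="session")
def small_sim_tags(small_sim):
    config, transcripts, truth, reads = small_sim
    raw = [RawRead(*r) for r in reads]
    return collapse(clean_reads(raw, config.adapter_seq))
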