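import numpy as np
import pandas as pd
import pytest

from knmir.discover import discover_candidates
from knmir.simulate import (SimConfig, TruthSet, generate_genome,
                            simulate_cohort, simulate_reads)


@pytest.fixture(scope="session")
def small_sim():
    """One synthetic dataset shared by read-evidence tests: 20 hairpins,
    20 decoys, depth 50."""
    cfg = SimConfig(seed=3, n_true_hairpins=20, n_decoy_loci=20,
                    genome_length=200_000, read_depth_per_locus=50)
    genome, truth = generate_genome(cfg)
    reads = simulate_reads(genome, truth, cfg)
    return cfg, genome, truth, reads


@pytest.fixture(scope="session")
def small_candidates(small_sim):
    cfg, genome, truth, reads = small_sim
    return discover_candidates(reads, genome, seed=cfg.seed)


def null_cohort(seed: int, n_loci: int = 100, n_pairs: int = 30,
                **cfg_kwargs) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """A tumour/normal cohort with no planted effects (helper used by
    calibration tests)."""
    ids = [f"hp{i:03d}" for i in range(n_loci)]
    hp = pd.DataFrame({"id": ids, "chrom": "chr1", "start": 0, "end": 1,
                       "strand": "+", "mature_start": 0, "mature_end": 22,
                       "precursor_seq": "", "mature_seq": ""})
    truth = TruthSet(hairpin_loci=hp, decoy_loci=pd.DataFrame(
        columns=["id", "chrom", "start", "end", "strand", "kind"]))
    truth.de_truth = {i: 0.0 for i in ids}
    cfg = SimConfig(seed=seed, n_pairs=n_pairs, **cfg_kwargs)
    counts, ann = simulate_cohort(truth, cfg)
    return counts, ann, truth


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
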