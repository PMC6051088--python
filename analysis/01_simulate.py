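"""Generate the synthetic study: genome with planted hairpins and
decoys, Dicer-like read stacks, a 71-pair tumour/normal cohort with
planted fold changes, and survival times with a planted hazard ratio.

Writes results/data/. Rerunning with the same seed reproduces every
file byte for byte.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))
from acceptance import build_config  # noqa: E402

from knmir import io as kio  # noqa: E402
from knmir.simulate import (generate_genome, simulate_cohort,  # noqa: E402
                            simulate_reads)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

cfg = build_config(seed=1).sim
genome, truth = generate_genome(cfg)
reads = simulate_reads(genome, truth, cfg)
counts, annotations = simulate_cohort(truth, cfg)

kio.write_fasta(OUT / "genome.fa", {cfg.chrom: genome})
truth.hairpin_loci.to_csv(OUT / "truth_hairpins.tsv", sep="\t", index=False)
truth.decoy_loci.to_csv(OUT / "truth_decoys.tsv", sep="\t", index=False)
kio.write_bed(OUT / "rrna_trna.bed", truth.decoy_loci.rename(columns={"kind": "name"}))
kio.write_read_table(OUT / "reads.tsv", reads)
counts.to_csv(OUT / "truth_counts.tsv", sep="\t")
annotations.to_csv(OUT / "annotations.tsv", sep="\t", index=False)
pd.Series(truth.de_truth, name="log2fc").rename_axis("locus").to_csv(
    OUT / "de_truth.tsv", sep="\t")

n_de = sum(v != 0 for v in truth.de_truth.values())
print(f"simulated {len(genome):,} nt genome: {len(truth.hairpin_loci)} hairpins "
      f"({n_de} with planted fold changes), {len(truth.decoy_loci)} rRNA/tRNA decoys")
print(f"{len(reads):,} reads; cohort of {cfg.n_pairs} tumour/normal pairs; "
      f"hazard ratio {cfg.hazard_ratio_high_vs_low} planted on {list(cfg.survival_loci)}")
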