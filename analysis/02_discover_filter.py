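"""Discover hairpin candidates from the read stacks, run the manual
filter cascade, and assign Knm IDs.

Reads results/data/, writes results/discovery/. The filter report shows
how many candidates each step removed; with clean synthetic data the
background read loci fall at the >= 10-read step and decoys at the
rRNA/tRNA-overlap and structure-p steps.
"""
from pathlib import Path

import pandas as pd

from knmir import io as kio
from knmir.discover import candidates_to_frame, discover_candidates
from knmir.filters import apply_filter_cascade, assign_ids

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "discovery"
OUT.mkdir(parents=True, exist_ok=True)

genome = next(iter(kio.read_fasta(DATA / "genome.fa").values()))
reads = kio.read_read_table(DATA / "reads.tsv")
decoys = kio.read_bed(DATA / "rrna_trna.bed")

candidates = discover_candidates(reads, genome, seed=2)
candidates_to_frame(candidates).to_csv(OUT / "candidates.tsv", sep="\t", index=False)

retained, report = apply_filter_cascade(candidates, decoys, known_mirna_fasta={})
retained = assign_ids(retained)
report.to_frame().to_csv(OUT / "filter_report.tsv", sep="\t", index=False)
frame = candidates_to_frame(retained)
frame.to_csv(OUT / "retained_candidates.tsv", sep="\t", index=False)
kio.write_fasta(OUT / "retained_mature.fa",
                {c.knm_id: c.mature_seq for c in retained})

truth = pd.read_csv(DATA / "truth_hairpins.tsv", sep="\t")
hits = sum(((frame["start"] < r["end"]) & (r["start"] < frame["end"])).any()
           for _, r in truth.iterrows())
print(f"{len(candidates)} candidates discovered")
for step, n_in, n_out in report.per_step:
    print(f"  {step:20s} {n_in:4d} -> {n_out:4d}")
print(f"{len(retained)} retained; {hits}/{len(truth)} planted hairpins recovered")
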