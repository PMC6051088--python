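"""Target prediction for the differentially expressed miRNAs against
3'UTRs with planted complementary sites, the five-scramble null filter,
>=10% aggregation, and hypergeometric pathway enrichment.

Reads results/expression/ and results/discovery/, writes
results/targets/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from knmir import io as kio
from knmir.enrich import enrich
from knmir.plots import enrichment_barplot
from knmir.simulate import SimConfig, plant_target_sites
from knmir.targets import (aggregate_targets, predictions_to_frame,
                           scramble_null_filter)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "targets"
OUT.mkdir(parents=True, exist_ok=True)

de = pd.read_csv(ROOT / "expression" / "de.tsv", sep="\t")
mature = kio.read_fasta(ROOT / "discovery" / "retained_mature.fa")
sig = de[de["bh_p"] < 0.05]["locus"]
mirnas = {mid: mature[mid].replace("T", "U") for mid in sig if mid in mature}

site_cfg = SimConfig(seed=3, n_utrs=200, planted_sites_per_mirna=2,
                     target_hub_genes=12)
utrs, target_truth = plant_target_sites(mirnas, site_cfg)
kio.write_fasta(OUT / "utrs.fa", utrs)
pd.DataFrame(target_truth, columns=["mirna", "gene"]).to_csv(
    OUT / "target_truth.tsv", sep="\t", index=False)

rng = np.random.default_rng(23)
per_mirna = {mid: scramble_null_filter(mid, seq, utrs,
                                       seed=int(rng.integers(2 ** 31)))
             for mid, seq in mirnas.items()}
preds = [p for ps in per_mirna.values() for p in ps]
predictions_to_frame(preds).to_csv(OUT / "targets.tsv", sep="\t", index=False)
genes = aggregate_targets(per_mirna)
pd.Series(genes, name="gene").to_csv(OUT / "aggregated_genes.tsv", sep="\t",
                                     index=False)

# synthetic pathway sets: one collecting the planted target genes,
# the rest random draws from the UTR gene universe
universe = sorted(utrs)
prng = np.random.default_rng(31)
pathways = {"PLANTED_TARGETS": {g for _, g in target_truth}
            | set(prng.choice(universe, size=10, replace=False))}
for i in range(19):
    pathways[f"RANDOM_{i + 1:02d}"] = set(
        prng.choice(universe, size=int(prng.integers(10, 40)), replace=False))
lines = [f"{name}\tsynthetic\t" + "\t".join(sorted(members))
         for name, members in pathways.items()]
(OUT / "pathways.gmt").write_text("\n".join(lines) + "\n")

query = set(genes) & set(universe)
res = enrich(query, pathways, universe=set(universe))
res.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
enrichment_barplot(res, OUT / "enrichment.png")

found = {(m, p.gene) for m, ps in per_mirna.items() for p in ps}
planted = set(target_truth)
print(f"{len(mirnas)} DE miRNAs queried against {len(utrs)} UTRs")
print(f"{len(preds)} predictions survive score>=140, energy<=-20 and the "
      f"five-scramble null; {len(planted & found)}/{len(planted)} planted sites recovered")
print(f"{len(genes)} genes targeted by >=10% of the miRNAs")
top = res.iloc[0]
print(f"top pathway: {top['pathway']} (overlap {top['n_overlap']}, "
      f"BH-p={top['bh_p']:.3g}); {int(res['significant'].sum())} pathways at BH-p<=0.05")
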