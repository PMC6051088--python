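"""Synthetic ground-truth data for the novel-miRNA discovery pipeline.

Every input the pipeline consumes can be generated here with planted
truth: a genome carrying inverted-repeat hairpin precursors and
structureless decoy loci, Dicer-like read stacks over the hairpins,
smeared reads over decoys, Poisson background reads, a paired
tumour/normal cohort with negative-binomial counts and planted fold
changes, exponential survival times whose hazard depends on planted
expression tertiles, and 3'UTRs with planted perfectly complementary
target sites.

Coordinates are 0-based half-open throughout (BED-compatible). All
randomness flows through one numpy Generator seeded from SimConfig.seed,
so a fixed seed reproduces every output byte-for-byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

DNA = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGT", "TGCA")
DNA2RNA = str.maketrans("T", "U")
RNA2DNA = str.maketrans("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(str.maketrans("ACGU", "UGCA"))[::-1]


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults emulate the cohort structure the pipeline targets: a panel
    of hairpin loci read out at moderate depth, decoy rRNA/tRNA-like
    loci, 71 tumour/normal pairs with negative-binomial counts, and
    exponential survival with a planted high-vs-low hazard ratio.
    """

    seed: int = 0
    n_true_hairpins: int = 30
    n_decoy_loci: int = 30
    genome_length: int = 200_000
    read_depth_per_locus: int = 50
    background_read_rate: float = 0.5  # reads per kb
    n_pairs: int = 71
    nb_dispersion: float = 0.1
    planted_log2fc: dict[str, float] = field(default_factory=dict)  # locus id -> log2 FC
    default_log2fc: float = 0.0
    baseline_hazard: float = 1.0 / 1200.0  # per day
    hazard_ratio_high_vs_low: float = 1.0
    survival_loci: tuple[str, ...] = ()  # loci whose top tertile carries the hazard ratio
    censor_rate: float = 0.3
    followup_horizon_days: float = 3650.0
    n_utrs: int = 200
    planted_sites_per_mirna: int = 1
    # when > 0, planted sites are drawn from a shared pool of this many
    # "hub" genes so that genes accumulate sites from several miRNAs
    # (the target-aggregation rule needs shared targets to fire)
    target_hub_genes: int = 0
    # extra null features in the count matrix standing in for the
    # annotated small-RNA complement; TMM normalization is anchored on
    # them so that a high planted-DE fraction among the novel loci does
    # not bias the scaling factors
    n_background_features: int = 0
    base_mean: float = 200.0  # mean normal-tissue count per locus
    arm_length: int = 30
    loop_length: int = 8
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        for name in ("n_true_hairpins", "n_decoy_loci", "genome_length",
                     "read_depth_per_locus", "n_pairs", "n_utrs",
                     "planted_sites_per_mirna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside each synthetic dataset."""

    hairpin_loci: pd.DataFrame  # id, chrom, start, end, strand, mature_start, mature_end, precursor_seq, mature_seq
    decoy_loci: pd.DataFrame    # id, chrom, start, end, strand, kind (rRNA/tRNA)
    de_truth: dict[str, float] = field(default_factory=dict)
    survival_truth: dict[str, float] = field(default_factory=dict)
    target_truth: list[tuple[str, str]] = field(default_factory=list)


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(DNA, size=length)


def generate_genome(cfg: SimConfig) -> tuple[str, TruthSet]:
    """Random genome with planted hairpin precursors and decoy loci.

    Each precursor is arm + loop + reverse-complement(arm), so refolding
    recovers a stem of at least ``arm_length`` pairings around a loop of
    ``loop_length`` nt. Decoys are plain intervals of the random
    background labelled rRNA or tRNA.
    """
    n_loci = cfg.n_true_hairpins + cfg.n_decoy_loci
    prec_len = 2 * cfg.arm_length + cfg.loop_length
    if n_loci and cfg.genome_length < 10 * n_loci * 120:
        raise ValueError(
            f"genome_length={cfg.genome_length} too small to pack {n_loci} loci; "
            f"need >= {10 * n_loci * 120}"
        )
    rng = cfg.rng()
    genome = _random_genome(rng, cfg.genome_length)

    slot = 400  # non-overlap spacing between planted loci
    n_slots = cfg.genome_length // slot
    chosen = rng.choice(n_slots, size=n_loci, replace=False) if n_loci else np.array([], int)
    hp_rows, decoy_rows = [], []
    for idx, s in enumerate(chosen):
        offset = int(rng.integers(0, slot - prec_len - 10))
        start = int(s) * slot + offset
        if idx < cfg.n_true_hairpins:
            arm = "".join(rng.choice(DNA, size=cfg.arm_length))
            loop = "".join(rng.choice(DNA, size=cfg.loop_length))
            prec = arm + loop + revcomp_dna(arm)
            genome[start:start + prec_len] = list(prec)
            mature_start = start  # 5' arm, first 22 nt
            hp_rows.append({
                "id": f"hp{idx + 1:03d}", "chrom": cfg.chrom,
                "start": start, "end": start + prec_len, "strand": "+",
                "mature_start": mature_start, "mature_end": mature_start + 22,
                "precursor_seq": prec.translate(DNA2RNA),
                "mature_seq": prec[:22].translate(DNA2RNA),
            })
        else:
            kind = "rRNA" if (idx - cfg.n_true_hairpins) % 2 == 0 else "tRNA"
            decoy_rows.append({
                "id": f"decoy{idx - cfg.n_true_hairpins + 1:03d}", "chrom": cfg.chrom,
                "start": start, "end": start + prec_len, "strand": "+", "kind": kind,
            })
    hp_cols = ["id", "chrom", "start", "end", "strand", "mature_start",
               "mature_end", "precursor_seq", "mature_seq"]
    dc_cols = ["id", "chrom", "start", "end", "strand", "kind"]
    truth = TruthSet(
        hairpin_loci=pd.DataFrame(hp_rows, columns=hp_cols).sort_values("start", ignore_index=True),
        decoy_loci=pd.DataFrame(decoy_rows, columns=dc_cols).sort_values("start", ignore_index=True),
    )
    truth.de_truth = {
        r: cfg.planted_log2fc.get(r, cfg.default_log2fc) for r in truth.hairpin_loci["id"]
    }
    truth.survival_truth = {
        r: (cfg.hazard_ratio_high_vs_low if r in cfg.survival_loci else 1.0)
        for r in truth.hairpin_loci["id"]
    }
    return "".join(genome), truth


def simulate_reads(genome: str, truth: TruthSet, cfg: SimConfig,
                   sample_id: str = "pool") -> pd.DataFrame:
    """Read placements emulating Dicer processing evidence.

    True hairpins get a dominant mature-arm stack (>= 80% of the stack
    sharing one 5' end, small +/-1 jitter otherwise) plus a minor
    star-arm stack; decoys get the same depth smeared uniformly with
    heterogeneous 5' ends; background reads arrive as a Poisson process
    along the genome at ``background_read_rate`` per kb.
    """
    if cfg.read_depth_per_locus <= 0 and len(truth.hairpin_loci):
        raise ValueError("read_depth_per_locus must be positive when hairpins are planted")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    rows = []
    rid = 0

    def emit(start: int, length: int) -> None:
        nonlocal rid
        rid += 1
        end = min(start + length, len(genome))
        rows.append({
            "read_id": f"r{rid:07d}", "chrom": cfg.chrom, "start": start,
            "end": end, "strand": "+", "sequence": genome[start:end],
            "sample": sample_id,
        })

    depth = cfg.read_depth_per_locus
    for _, hp in truth.hairpin_loci.iterrows():
        m0 = int(hp["mature_start"])
        # mature stack: depth reads, ~88% at the modal 5' end
        for _ in range(depth):
            jitter = 0 if rng.random() < 0.88 else int(rng.choice([-1, 1]))
            emit(m0 + jitter, int(rng.integers(21, 24)))
        # minor star stack on the 3' arm (2-nt 3' overhang geometry)
        star0 = int(hp["end"]) - 22 - 2
        for _ in range(max(1, depth // 4)):
            jitter = 0 if rng.random() < 0.88 else int(rng.choice([-1, 1]))
            emit(star0 + jitter, int(rng.integers(21, 24)))
    for _, dc in truth.decoy_loci.iterrows():
        lo, hi = int(dc["start"]), int(dc["end"])
        for _ in range(depth):
            length = int(rng.integers(18, 31))
            emit(int(rng.integers(lo, hi - 17)), length)
    n_bg = rng.poisson(cfg.background_read_rate * len(genome) / 1000.0)
    for _ in range(n_bg):
        emit(int(rng.integers(0, len(genome) - 22)), 22)
    cols = ["read_id", "chrom", "start", "end", "strand", "sequence", "sample"]
    return pd.DataFrame(rows, columns=cols)


def simulate_cohort(truth: TruthSet, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumour/normal counts plus per-patient survival annotations.

    Counts are negative binomial with variance mu + dispersion * mu^2;
    tumour means are scaled by 2**log2fc. Survival times are exponential
    with the baseline hazard multiplied by ``hazard_ratio_high_vs_low``
    for patients in the top tumour-expression tertile of each locus in
    ``survival_loci``; censoring is an independent exponential competing
    time plus an administrative horizon.
    """
    if cfg.n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if cfg.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    loci = list(truth.hairpin_loci["id"]) \
        + [f"bg{i + 1:04d}" for i in range(cfg.n_background_features)]
    n = cfg.n_pairs
    samples = [f"P{i + 1:03d}{c}" for i in range(n) for c in ("N", "T")]

    def nb(mean: np.ndarray) -> np.ndarray:
        # numpy NB: n = 1/dispersion, p = n/(n+mu)
        size = 1.0 / cfg.nb_dispersion
        return rng.negative_binomial(size, size / (size + mean))

    counts = np.zeros((len(loci), 2 * n), dtype=np.int64)
    base_means = cfg.base_mean * rng.lognormal(0.0, 0.5, size=len(loci))
    for li, locus in enumerate(loci):
        fc = 2.0 ** truth.de_truth.get(locus, 0.0)
        mu_n = np.full(n, base_means[li])
        counts[li, 0::2] = nb(mu_n)
        counts[li, 1::2] = nb(mu_n * fc)
    count_df = pd.DataFrame(counts, index=pd.Index(loci, name="locus"), columns=samples)

    # survival: one record per pair (the tumour patient)
    hazard = np.full(n, cfg.baseline_hazard)
    for locus in cfg.survival_loci:
        if locus not in loci:
            continue
        expr = counts[loci.index(locus), 1::2].astype(float)
        order = np.argsort(-expr, kind="stable")
        top = order[: n // 3]
        hazard[top] *= cfg.hazard_ratio_high_vs_low
    death = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0 and cfg.censor_rate < 1:
        c_rate = cfg.baseline_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        censor = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, cfg.followup_horizon_days)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    ann_rows = []
    for i in range(n):
        for c, cond in (("N", "normal"), ("T", "tumour")):
            ann_rows.append({
                "sample": f"P{i + 1:03d}{c}", "pair": f"P{i + 1:03d}",
                "condition": cond, "time_days": float(time[i]), "event": int(event[i]),
            })
    annotations = pd.DataFrame(ann_rows)
    return count_df, annotations


def plant_target_sites(mirna_sequences: dict[str, str], cfg: SimConfig
                       ) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Random 3'UTRs with planted perfectly complementary miRNA sites.

    Each planted site is the exact reverse complement of the full miRNA
    embedded at a random position of a dedicated target UTR; untargeted
    UTRs are plain random sequence. Returns (utr id -> RNA sequence,
    list of planted (miRNA id, gene id) pairs).
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    for mid, seq in mirna_sequences.items():
        if not set(seq) <= set("ACGU") or not 18 <= len(seq) <= 25:
            raise ValueError(f"miRNA {mid} must be RNA of length 18-25")
    n_sites = cfg.planted_sites_per_mirna * len(mirna_sequences)
    needed = cfg.target_hub_genes if cfg.target_hub_genes > 0 else n_sites
    if cfg.n_utrs < needed:
        raise ValueError("n_utrs too small for the requested planted sites")
    lengths = rng.integers(400, 1201, size=cfg.n_utrs)
    utrs = {
        f"GENE{i + 1:04d}": "".join(rng.choice(list("ACGU"), size=int(L)))
        for i, L in enumerate(lengths)
    }
    gene_ids = list(utrs)
    target_truth: list[tuple[str, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}

    def insert_site(mid: str, gid: str, site: str) -> None:
        utr = utrs[gid]
        if len(utr) < len(site):
            raise ValueError(f"UTR {gid} shorter than miRNA {mid}")
        for _ in range(100):
            pos = int(rng.integers(0, len(utr) - len(site) + 1))
            if all(pos + len(site) <= a or b <= pos for a, b in occupied[gid]):
                break
        else:
            raise ValueError(f"could not place a site in UTR {gid}")
        utrs[gid] = utr[:pos] + site + utr[pos + len(site):]
        occupied[gid].append((pos, pos + len(site)))
        target_truth.append((mid, gid))

    if n_sites and cfg.target_hub_genes > 0:
        if cfg.target_hub_genes < cfg.planted_sites_per_mirna:
            raise ValueError("target_hub_genes must be >= planted_sites_per_mirna")
        pool = [gene_ids[i] for i in
                rng.choice(len(gene_ids), size=cfg.target_hub_genes, replace=False)]
        for mid, mseq in mirna_sequences.items():
            site = revcomp_rna(mseq)
            picks = rng.choice(len(pool), size=cfg.planted_sites_per_mirna,
                               replace=False)
            for k in picks:
                insert_site(mid, pool[int(k)], site)
    elif n_sites:
        chosen = rng.choice(len(gene_ids), size=n_sites, replace=False)
        k = 0
        for mid, mseq in mirna_sequences.items():
            site = revcomp_rna(mseq)
            for _ in range(cfg.planted_sites_per_mirna):
                insert_site(mid, gene_ids[int(chosen[k])], site)
                k += 1
    return utrs, target_truth


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["survival_loci"] = list(cfg.survival_loci)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "survival_loci" in d:
        d["survival_loci"] = tuple(d["survival_loci"])
    return SimConfig(**d)
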