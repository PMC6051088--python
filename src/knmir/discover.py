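"""Hairpin candidate discovery from stacked small-RNA read evidence.

Reads are merged into loci, each locus is folded with a weighted
base-pair maximization DP, the fold is tested against
dinucleotide-preserving shuffles (a randfold-style p-value), and a
read-signature score measures how Dicer-like the read stack is
(mature/star/loop partition with homogeneous 5' ends). Loci whose
mature arm sits on a stem and whose signature clears the cutoff are
emitted as HairpinCandidates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from ._fold import encode_rna, pairing_dp, traceback, pair_table
from ._shuffle import dinucleotide_shuffle
from .simulate import DNA2RNA

DEFAULT_MIN_LOOP = 3
DEFAULT_MAX_PRECURSOR = 120
DEFAULT_MAX_GAP = 30
DEFAULT_SIGNATURE_CUTOFF = 0.6
DEFAULT_FLANK = 10


@dataclass
class ReadLocus:
    chrom: str
    start: int
    end: int
    strand: str
    per_position_depth: np.ndarray
    distinct_reads: list[tuple[str, int, int]]  # (sequence, start, count)
    total_reads: int

    def __post_init__(self) -> None:
        assert self.total_reads == sum(c for _, _, c in self.distinct_reads)


@dataclass
class HairpinCandidate:
    locus: ReadLocus
    precursor_start: int
    precursor_seq: str
    structure: str
    pairing_score: int
    mature_seq: str
    mature_start: int  # genomic
    star_seq: str
    signature_score: float
    gc_fraction: float
    randfold_p: float = float("nan")
    knm_id: str | None = None

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def locus_reads(self) -> int:
        return self.locus.total_reads


def stack_reads(read_table: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP,
                max_precursor_length: int = DEFAULT_MAX_PRECURSOR) -> list[ReadLocus]:
    """Merge same-strand reads into loci; split over-long loci at the
    deepest coverage valley until every locus fits a precursor."""
    required = {"chrom", "start", "end", "strand", "sequence"}
    missing = required - set(read_table.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    if len(read_table) == 0:
        return []
    if (read_table["start"] < 0).any() or (read_table["end"] <= read_table["start"]).any():
        raise ValueError("malformed read coordinates (need 0 <= start < end)")

    loci: list[ReadLocus] = []
    tab = read_table.sort_values(["chrom", "strand", "start", "end"], kind="stable")
    for (chrom, strand), grp in tab.groupby(["chrom", "strand"], sort=True):
        block: list[tuple[int, int, str]] = []
        block_end = None
        for start, end, seq in zip(grp["start"], grp["end"], grp["sequence"]):
            if block and start - block_end > max_gap:
                loci.extend(_finalize(chrom, strand, block, max_precursor_length))
                block = []
            block.append((int(start), int(end), seq))
            block_end = int(end) if block_end is None or len(block) == 1 else max(block_end, int(end))
        if block:
            loci.extend(_finalize(chrom, strand, block, max_precursor_length))
    return loci


def _finalize(chrom: str, strand: str, block: list[tuple[int, int, str]],
              max_len: int) -> list[ReadLocus]:
    lo = min(s for s, _, _ in block)
    hi = max(e for _, e, _ in block)
    depth = np.zeros(hi - lo, dtype=np.int64)
    for s, e, _ in block:
        depth[s - lo:e - lo] += 1
    if hi - lo > max_len:
        # split at the deepest coverage valley (interior minimum)
        interior = depth[1:-1]
        cut = lo + 1 + int(np.argmin(interior))
        left = [r for r in block if r[0] < cut]
        right = [r for r in block if r[0] >= cut]
        if left and right:
            return (_finalize(chrom, strand, left, max_len)
                    + _finalize(chrom, strand, right, max_len))
        # all reads on one side: clip to max_len around the densest point
    counts = Counter((seq, s) for s, _, seq in block)
    distinct = sorted(((seq, s, c) for (seq, s), c in counts.items()),
                      key=lambda t: (t[1], t[0]))
    return [ReadLocus(chrom, lo, hi, strand, depth, distinct, len(block))]


def fold_hairpin(seq: str, min_loop: int = DEFAULT_MIN_LOOP) -> tuple[str, int]:
    """Maximum-weight nested structure (G-C=3, A-U=2, G-U=1).

    Returns (dot-bracket structure, pairing score). Deterministic: ties
    resolve toward pairing with the smallest admissible partner.
    """
    codes = encode_rna(seq)
    if len(codes) == 0:
        return "", 0
    dp = pairing_dp(codes, min_loop)
    return traceback(codes, dp, min_loop), int(dp[0, len(codes) - 1])


def randfold_pvalue(seq: str, n_shuffles: int = 99, seed: int | np.random.Generator = 0,
                    min_loop: int = DEFAULT_MIN_LOOP) -> float:
    """Shuffle-based structure p-value, p = (c + 1) / (n + 1).

    c counts dinucleotide-preserving shuffles whose pairing score is at
    least the observed score; the +1s make p exact and strictly
    positive (minimum 1/(n_shuffles + 1)).
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    if len(seq) < 4:
        raise ValueError("sequence too short to shuffle (< 4 nt)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = encode_rna(seq)
    observed = int(pairing_dp(codes, min_loop)[0, len(codes) - 1])
    c = 0
    for _ in range(n_shuffles):
        sh = dinucleotide_shuffle(seq, rng)
        sc = encode_rna(sh)
        if int(pairing_dp(sc, min_loop)[0, len(sc) - 1]) >= observed:
            c += 1
    return (c + 1) / (n_shuffles + 1)


def _modal_stack(locus: ReadLocus) -> tuple[int, int, int]:
    """(modal 5' start, count at modal start, modal read length there)."""
    by_start: Counter[int] = Counter()
    for _, s, c in locus.distinct_reads:
        by_start[s] += c
    modal_start = min(s for s, c in by_start.items() if c == max(by_start.values()))
    lengths = Counter()
    for seq, s, c in locus.distinct_reads:
        if s == modal_start:
            lengths[len(seq)] += c
    modal_len = min(l for l, c in lengths.items() if c == max(lengths.values()))
    return modal_start, by_start[modal_start], modal_len


def score_candidate(locus: ReadLocus, genome: str,
                    min_loop: int = DEFAULT_MIN_LOOP,
                    flank: int = DEFAULT_FLANK,
                    max_precursor_length: int = DEFAULT_MAX_PRECURSOR,
                    signature_cutoff: float = DEFAULT_SIGNATURE_CUTOFF,
                    ) -> HairpinCandidate | None:
    """Fold the locus and score its Dicer signature.

    The mature arm is the deepest read stack; the star is the stem
    partner of the mature with a 2-nt 3' overhang. The signature score
    is (fraction of reads whose 5' end falls within 2 nt of the mature
    or star start) times (5'-end homogeneity of the mature stack).
    Returns None when the mature does not sit on a stem or the
    signature misses the cutoff.
    """
    if locus.total_reads == 0:
        raise ValueError("locus has no reads")
    p_start = max(0, locus.start - flank)
    p_end = min(len(genome), locus.end + flank)
    if p_end - p_start > max_precursor_length:
        p_end = p_start + max_precursor_length
    precursor = genome[p_start:p_end].translate(DNA2RNA)
    structure, score = fold_hairpin(precursor, min_loop)
    partner = pair_table(structure)

    modal_start, modal_count, modal_len = _modal_stack(locus)
    m0 = modal_start - p_start
    m1 = min(m0 + modal_len, len(precursor))
    if m0 < 0 or m1 - m0 < 15:
        return None
    mature_seq = precursor[m0:m1]

    # mature must lie on a stem: at least half its bases paired
    m_pairs = [i for i in range(m0, m1) if partner[i] >= 0]
    if len(m_pairs) < (m1 - m0) / 2:
        return None
    partners = sorted(partner[i] for i in m_pairs)
    s_lo, s_hi = partners[0], partners[-1] + 1
    # 2-nt 3' overhang on the star side
    if s_lo >= m1:        # mature on 5' arm; star 3' end shifts +2
        s_hi = min(len(precursor), s_hi + 2)
    else:                 # mature on 3' arm; star is 5' arm
        s_lo = max(0, s_lo - 0)
        s_hi = min(m0, s_hi + 2)
    if s_lo < m1 and s_hi > m0:  # overlap with mature: clip
        if s_lo >= m0:
            return None
        s_hi = min(s_hi, m0)
    star_seq = precursor[s_lo:s_hi]

    # signature: read starts consistent with the mature or star 5' end
    star_start_genomic = p_start + s_lo
    consistent = 0
    mature_stack = 0
    for _, s, c in locus.distinct_reads:
        if abs(s - modal_start) <= 2:
            consistent += c
            mature_stack += c
        elif abs(s - star_start_genomic) <= 2:
            consistent += c
    homogeneity = modal_count / mature_stack if mature_stack else 0.0
    signature = (consistent / locus.total_reads) * homogeneity

    gc = (mature_seq.count("G") + mature_seq.count("C")) / len(mature_seq)
    cand = HairpinCandidate(
        locus=locus, precursor_start=p_start, precursor_seq=precursor,
        structure=structure, pairing_score=score, mature_seq=mature_seq,
        mature_start=modal_start, star_seq=star_seq,
        signature_score=signature, gc_fraction=gc,
    )
    if signature < signature_cutoff:
        return None
    return cand


def discover_candidates(read_table: pd.DataFrame, genome: str, *,
                        max_gap: int = DEFAULT_MAX_GAP,
                        max_precursor_length: int = DEFAULT_MAX_PRECURSOR,
                        min_loop: int = DEFAULT_MIN_LOOP,
                        signature_cutoff: float = DEFAULT_SIGNATURE_CUTOFF,
                        n_shuffles: int = 99,
                        seed: int = 0) -> list[HairpinCandidate]:
    """Full discovery stage: stack, fold, shuffle-test, signature-score."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    out = []
    for locus in stack_reads(read_table, max_gap, max_precursor_length):
        cand = score_candidate(locus, genome, min_loop=min_loop,
                               max_precursor_length=max_precursor_length,
                               signature_cutoff=signature_cutoff)
        if cand is None:
            continue
        cand.randfold_p = randfold_pvalue(cand.precursor_seq, n_shuffles, rng, min_loop)
        out.append(cand)
    return out


def candidates_to_frame(candidates: list[HairpinCandidate]) -> pd.DataFrame:
    rows = [{
        "id": c.knm_id or f"cand{i + 1:04d}",
        "chrom": c.chrom, "start": c.locus.start, "end": c.locus.end,
        "strand": c.locus.strand, "locus_reads": c.locus_reads,
        "pairing_score": c.pairing_score, "randfold_p": c.randfold_p,
        "signature_score": c.signature_score, "gc_fraction": c.gc_fraction,
        "mature_seq": c.mature_seq, "star_seq": c.star_seq,
        "precursor_seq": c.precursor_seq, "structure": c.structure,
    } for i, c in enumerate(candidates)]
    return pd.DataFrame(rows)
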