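"""The manual filter cascade applied to hairpin candidates.

Six ordered steps, each recorded in an auditable FilterReport:

1. locus read support (>= 10 reads),
2. overlap with rRNA/tRNA annotation intervals (any 1-bp overlap drops
   the candidate),
3. shuffle-based structure p-value (< 0.05),
4. duplicate removal (identical mature sequences collapse to the
   highest-signature locus),
5. homology screen against known miRNAs (best Karlin-Altschul E-value
   < 0.1 means "already annotated", drop),
6. GC-content outlier removal (mature GC beyond 2 population SDs of the
   current set's mean).

Survivors receive Knm IDs: "Knm{chromosome number}_{serial}" with the
serial taken from (chrom, start)-sorted order over the retained set.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from .discover import HairpinCandidate


@dataclass
class FilterThresholds:
    min_locus_reads: int = 10
    structure_p_max: float = 0.05
    evalue_max: float = 0.1
    gc_sd_multiplier: float = 2.0
    min_total_reads: int = 10
    tmm_expression_min: float = 0.1

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


@dataclass
class FilterReport:
    per_step: list[tuple[str, int, int]] = field(default_factory=list)
    rejections: list[tuple[str, str, str]] = field(default_factory=list)  # id, step, reason

    def record(self, step: str, n_in: int, n_out: int) -> None:
        if self.per_step and self.per_step[-1][2] != n_in:
            raise ValueError("filter report counts do not telescope")
        if n_out > n_in:
            raise ValueError("a filter step cannot increase the candidate count")
        self.per_step.append((step, n_in, n_out))

    def reject(self, cand_id: str, step: str, reason: str) -> None:
        self.rejections.append((cand_id, step, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_step, columns=["step", "candidates_in", "candidates_out"])


# ---------------------------------------------------------------- homology

@lru_cache(maxsize=None)
def karlin_altschul_params(match: int = 1, mismatch: int = -2,
                           n_sigma_terms: int = 60) -> tuple[float, float]:
    """Ungapped Karlin-Altschul (lambda, K) for uniform base composition.

    lambda is the unique positive root of sum_ij p_i p_j exp(lambda s_ij)
    = 1. K comes from the lattice-case series: with step distribution
    P(s), H = lambda * E[s e^(lambda s)], delta the score lattice span,
    and sigma = sum_k (1/k) (E[e^(lambda S_k); S_k<0] + P(S_k>=0)) over
    k-step random-walk sums S_k,

        K = delta * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda delta))).

    Reproduces the published BLASTN ungapped constants (e.g. +1/-2 ->
    lambda 1.33, K 0.621).
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")
    probs = {match: 4.0 / 16.0, mismatch: 12.0 / 16.0}
    lam = brentq(lambda L: sum(p * math.exp(L * s) for s, p in probs.items()) - 1.0,
                 1e-9, 20.0)
    H = lam * sum(s * p * math.exp(lam * s) for s, p in probs.items())
    delta = math.gcd(abs(match), abs(mismatch))
    lo = min(probs)
    hi = max(probs)
    base = np.zeros(hi - lo + 1)
    for s, p in probs.items():
        base[s - lo] = p
    conv = np.array([1.0])
    offset = 0
    sigma = 0.0
    for k in range(1, n_sigma_terms + 1):
        conv = np.convolve(conv, base)
        offset += lo
        vals = offset + np.arange(len(conv))
        neg = vals < 0
        sigma += ((conv[neg] * np.exp(lam * vals[neg])).sum() + conv[~neg].sum()) / k
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return lam, K


def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def homology_evalue(query: str, database: dict[str, str], *,
                    match: int = 1, mismatch: int = -2,
                    gap_open: int = -5, gap_extend: int = -2) -> float:
    """Best (smallest) E-value of the query against a known-miRNA set.

    Smith-Waterman local alignment against every database entry; the
    best score S is converted with E = K m n exp(-lambda S), m = query
    length, n = total database length, using ungapped Karlin-Altschul
    parameters for the match/mismatch scores (a standard approximation
    for gapped scores at these conservative penalties). Empty database
    -> +inf (nothing to be homologous to).
    """
    if not query:
        raise ValueError("empty query sequence")
    if not database:
        return float("inf")
    q = query.replace("U", "T")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    best = 0.0
    total_n = 0
    for seq in database.values():
        s = seq.replace("U", "T")
        total_n += len(s)
        if s:
            best = max(best, float(aligner.score(q, s)))
    lam, K = karlin_altschul_params(match, mismatch)
    return K * len(query) * total_n * math.exp(-lam * best)


# ---------------------------------------------------------------- steps

def _overlaps_annotation(cand: HairpinCandidate, bed: pd.DataFrame) -> bool:
    sel = bed[bed["chrom"] == cand.chrom]
    return bool(((sel["start"] < cand.locus.end) & (cand.locus.start < sel["end"])).any())


def gc_outlier_filter(candidates: list[HairpinCandidate],
                      sd_multiplier: float = 2.0,
                      report: FilterReport | None = None,
                      ) -> list[HairpinCandidate]:
    """Drop candidates whose mature GC deviates > sd_multiplier
    population SDs from the current set's mean. Single pass."""
    if len(candidates) < 2:
        if candidates:
            import warnings
            warnings.warn("GC filter needs >= 2 candidates; passing through")
        return list(candidates)
    gc = np.array([c.gc_fraction for c in candidates])
    mean, sd = gc.mean(), gc.std()  # population SD (ddof=0)
    kept = []
    for c, g in zip(candidates, gc):
        if sd == 0 or abs(g - mean) <= sd_multiplier * sd:
            kept.append(c)
        elif report is not None:
            report.reject(_cid(c), "gc_outlier",
                          f"gc={g:.3f} beyond {sd_multiplier} SD of mean {mean:.3f}")
    return kept


def _cid(c: HairpinCandidate) -> str:
    return c.knm_id or f"{c.chrom}:{c.locus.start}-{c.locus.end}({c.locus.strand})"


def apply_filter_cascade(candidates: list[HairpinCandidate],
                         rrna_trna_bed: pd.DataFrame | None,
                         known_mirna_fasta: dict[str, str],
                         thresholds: FilterThresholds | None = None,
                         ) -> tuple[list[HairpinCandidate], FilterReport]:
    """Run the six filter steps in their fixed order; report everything."""
    th = thresholds or FilterThresholds()
    report = FilterReport()
    cur = list(candidates)

    # 1. read support
    n_in = len(cur)
    kept = []
    for c in cur:
        if c.locus_reads >= th.min_locus_reads:
            kept.append(c)
        else:
            report.reject(_cid(c), "read_support",
                          f"{c.locus_reads} < {th.min_locus_reads} reads")
    report.record("read_support", n_in, len(kept))
    cur = kept

    # 2. rRNA/tRNA overlap
    if rrna_trna_bed is None:
        raise ValueError("rRNA/tRNA annotation BED required for the decoy-overlap step")
    n_in = len(cur)
    kept = []
    for c in cur:
        if _overlaps_annotation(c, rrna_trna_bed):
            report.reject(_cid(c), "rrna_trna_overlap", "overlaps annotated rRNA/tRNA interval")
        else:
            kept.append(c)
    report.record("rrna_trna_overlap", n_in, len(kept))
    cur = kept

    # 3. structure p-value
    n_in = len(cur)
    kept = []
    for c in cur:
        if np.isnan(c.randfold_p):
            report.reject(_cid(c), "structure_p", "missing shuffle p-value")
        elif c.randfold_p < th.structure_p_max:
            kept.append(c)
        else:
            report.reject(_cid(c), "structure_p",
                          f"p={c.randfold_p:.3g} >= {th.structure_p_max}")
    report.record("structure_p", n_in, len(kept))
    cur = kept

    # 4. duplicate mature sequences -> keep highest signature
    n_in = len(cur)
    best: dict[str, HairpinCandidate] = {}
    for c in cur:
        prev = best.get(c.mature_seq)
        if prev is None or (c.signature_score, -c.locus.start) > (prev.signature_score, -prev.locus.start):
            if prev is not None:
                report.reject(_cid(prev), "duplicates", "duplicate mature sequence")
            best[c.mature_seq] = c
        else:
            report.reject(_cid(c), "duplicates", "duplicate mature sequence")
    kept = [c for c in cur if best.get(c.mature_seq) is c]
    report.record("duplicates", n_in, len(kept))
    cur = kept

    # 5. homology to known miRNAs
    n_in = len(cur)
    kept = []
    for c in cur:
        e = homology_evalue(c.mature_seq, known_mirna_fasta)
        if e < th.evalue_max:
            report.reject(_cid(c), "known_homology", f"E={e:.3g} < {th.evalue_max}")
        else:
            kept.append(c)
    report.record("known_homology", n_in, len(kept))
    cur = kept

    # 6. GC outliers
    n_in = len(cur)
    cur = gc_outlier_filter(cur, th.gc_sd_multiplier, report)
    report.record("gc_outlier", n_in, len(cur))

    return cur, report


def assign_ids(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Knm{chromosome number}_{serial}; serial is 1-based rank in
    (chrom, start)-sorted order over the whole retained set."""
    keys = [(c.chrom, c.locus.start, c.locus.strand) for c in candidates]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (chrom, start, strand) after deduplication")
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i].chrom, candidates[i].locus.start))
    for serial, i in enumerate(order, start=1):
        c = candidates[i]
        m = re.search(r"(\d+|[XYM])$", c.chrom)
        chrom_label = m.group(1) if m else c.chrom
        c.knm_id = f"Knm{chrom_label}_{serial}"
    return candidates
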