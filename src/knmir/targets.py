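"""miRNA -> 3'UTR target prediction with a scrambled-sequence null.

A miRNA is aligned antiparallel against each UTR with a Smith-Waterman
local DP on complementarity (not identity): Watson-Crick pairs score
+5, G:U wobbles +1, mismatches -3, affine gaps -9/-4, and pair scores
at seed positions 2-8 of the miRNA are multiplied by 4. Duplex
stability is scored with Turner 2004 nearest-neighbor stacking energies
plus a flat +3.0 kcal/mol per interior loop or bulge and +4.09 duplex
initiation. Predictions must clear an alignment score >= 140 and an
energy <= -20 kcal/mol, and additionally survive a null built from five
scrambled copies of the miRNA: any gene also predicted for a scramble
is discarded.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from ._fold import RNA_CODE

SCORE_THRESHOLD = 140.0
ENERGY_THRESHOLD = -20.0
DUPLEX_INIT = 4.09
LOOP_PENALTY = 3.0

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class ScoringScheme:
    complementary: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2   # 1-based, inclusive
    seed_end: int = 8     # 1-based, inclusive
    seed_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if not self.complementary > self.wobble > self.mismatch:
            raise ValueError("need complementary > wobble > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass
class DuplexAlignment:
    score: float
    mirna_start: int  # 0-based, on the original miRNA, half-open
    mirna_end: int
    utr_start: int
    utr_end: int
    # aligned columns as (mirna index or -1, utr index or -1)
    columns: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class TargetPrediction:
    mirna: str
    gene: str
    utr_start: int
    utr_end: int
    alignment_score: float
    duplex_energy: float
    passed_scramble_null: bool = False


def _load_stacks() -> dict[tuple[str, str], float]:
    ref = importlib.resources.files("knmir.data") / "turner2004_stacks.tsv"
    tab = {}
    for line in ref.read_text().splitlines()[1:]:
        p1, p2, dg = line.split("\t")
        tab[(p1, p2)] = float(dg)
    return tab


STACK_DG = _load_stacks()


def _pair_code(a: str, b: str) -> int:
    if (a, b) in WC:
        return 2
    if (a, b) in WOBBLE:
        return 1
    return 0


@njit(cache=True)
def _sw_fill(S, gap_open, gap_extend):  # pragma: no cover - compiled
    """Affine-gap local DP. S is the (m x n) pair-score matrix.
    Returns H and pointer matrices (0 stop, 1 diag, 2 up/gap-in-utr,
    3 left/gap-in-mirna)."""
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), -1e18)  # gap in miRNA (left)
    F = np.full((m + 1, n + 1), -1e18)  # gap in UTR (up)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            best = 0.0
            p = 0
            if diag > best:
                best, p = diag, 1
            if F[i, j] > best:
                best, p = F[i, j], 2
            if E[i, j] > best:
                best, p = E[i, j], 3
            H[i, j] = best
            ptr[i, j] = p
    return H, E, F, ptr


_PAIR_CODE_TABLE = np.zeros((4, 4), dtype=np.int8)
for _a, _b in WC:
    _PAIR_CODE_TABLE[RNA_CODE[_a], RNA_CODE[_b]] = 2
for _a, _b in WOBBLE:
    _PAIR_CODE_TABLE[RNA_CODE[_a], RNA_CODE[_b]] = 1


def _score_matrix(mirna: str, utr: str, scheme: ScoringScheme,
                  masked: np.ndarray | None = None) -> np.ndarray:
    """Pair-score matrix for the reversed miRNA (rows) vs UTR (cols)."""
    m = len(mirna)
    cm = np.array([RNA_CODE[c] for c in mirna[::-1]])
    cu = np.array([RNA_CODE[c] for c in utr])
    code = _PAIR_CODE_TABLE[cm[:, None], cu[None, :]]
    S = np.where(code == 2, scheme.complementary,
                 np.where(code == 1, scheme.wobble, scheme.mismatch))
    orig = m - 1 - np.arange(m)  # original miRNA position per DP row
    in_seed = (orig >= scheme.seed_start - 1) & (orig <= scheme.seed_end - 1)
    S[in_seed, :] *= scheme.seed_multiplier
    if masked is not None:
        S[:, masked] = -1e9
    return S


def duplex_align(mirna: str, utr: str, scheme: ScoringScheme | None = None,
                 min_score: float = 0.0) -> list[DuplexAlignment]:
    """Non-overlapping local duplex alignments, best first.

    The miRNA is aligned antiparallel to the UTR: row k of the DP is the
    miRNA base at position len-1-k, so both aligned strings read 5'->3'
    along their own strands. Alignments are extracted greedily from the
    best DP cell down, masking the UTR footprint of each hit, until no
    alignment exceeds ``min_score``.
    """
    if not mirna or not utr:
        raise ValueError("empty sequence")
    for s, nm in ((mirna, "miRNA"), (utr, "UTR")):
        if not set(s) <= set(RNA_CODE):
            raise ValueError(f"non-RNA character in {nm}")
    scheme = scheme or ScoringScheme()
    m = len(mirna)
    masked = np.zeros(len(utr), dtype=bool)
    out: list[DuplexAlignment] = []
    while True:
        S = _score_matrix(mirna, utr, scheme, masked)
        H, E, F, ptr = _sw_fill(S, scheme.gap_open, scheme.gap_extend)
        i, j = np.unravel_index(np.argmax(H), H.shape)
        score = float(H[i, j])
        if score <= 0 or score < min_score:
            break
        cols: list[tuple[int, int]] = []
        while ptr[i, j] != 0 and H[i, j] > 0:
            p = ptr[i, j]
            if p == 1:
                cols.append((m - i, j - 1))
                i, j = i - 1, j - 1
            elif p == 2:
                # gap in UTR: consume miRNA rows back to the last H state
                while True:
                    cols.append((m - i, -1))
                    if H[i - 1, j] + scheme.gap_open == F[i, j] or i == 1:
                        i -= 1
                        break
                    i -= 1
            else:
                while True:
                    cols.append((-1, j - 1))
                    if H[i, j - 1] + scheme.gap_open == E[i, j] or j == 1:
                        j -= 1
                        break
                    j -= 1
        cols.reverse()
        mi = [c[0] for c in cols if c[0] >= 0]
        uj = [c[1] for c in cols if c[1] >= 0]
        if not mi or not uj:
            break
        aln = DuplexAlignment(score, min(mi), max(mi) + 1, min(uj), max(uj) + 1, cols)
        out.append(aln)
        masked[aln.utr_start:aln.utr_end] = True
        if masked.all():
            break
    return out


def duplex_energy(alignment: DuplexAlignment, mirna: str, utr: str) -> float:
    """Nearest-neighbor duplex free energy of an alignment, kcal/mol.

    Consecutive paired columns contribute their Turner 2004 stacking
    term; every interruption (mismatch column or gap run) between
    paired columns adds a flat +3.0 loop/bulge penalty; +4.09 duplex
    initiation. Requires at least two consecutive base pairs.
    """
    paired: list[tuple[int, int, int]] = []  # (col index, mi, uj)
    for idx, (mi, uj) in enumerate(alignment.columns):
        if mi >= 0 and uj >= 0 and _pair_code(mirna[mi], utr[uj]) > 0:
            paired.append((idx, mi, uj))
    if len(paired) < 2:
        raise ValueError("alignment has fewer than two base pairs; energy undefined")
    dg = DUPLEX_INIT
    has_stack = False
    for (i0, m0, u0), (i1, m1, u1) in zip(paired, paired[1:]):
        if i1 == i0 + 1 and abs(m1 - m0) == 1 and abs(u1 - u0) == 1:
            # contiguous stack; step read 5'->3' on the miRNA strand
            p1 = mirna[min(m0, m1)] + utr[max(u0, u1)]
            p2 = mirna[max(m0, m1)] + utr[min(u0, u1)]
            dg += STACK_DG[(p1, p2)]
            has_stack = True
        else:
            dg += LOOP_PENALTY
    if not has_stack:
        raise ValueError("alignment has no two consecutive base pairs; energy undefined")
    return dg


def predict_targets(mirna_id: str, mirna: str, utrs: dict[str, str], *,
                    scheme: ScoringScheme | None = None,
                    score_threshold: float = SCORE_THRESHOLD,
                    energy_threshold: float = ENERGY_THRESHOLD,
                    ) -> list[TargetPrediction]:
    """Predictions for one miRNA over a UTR set, thresholds enforced."""
    preds = []
    for gene, utr in utrs.items():
        for aln in duplex_align(mirna, utr, scheme, min_score=score_threshold):
            try:
                dg = duplex_energy(aln, mirna, utr)
            except ValueError:
                continue
            if aln.score >= score_threshold and dg <= energy_threshold:
                preds.append(TargetPrediction(mirna_id, gene, aln.utr_start,
                                              aln.utr_end, aln.score, dg))
    for p in preds:
        assert p.alignment_score >= score_threshold and p.duplex_energy <= energy_threshold
    return preds


def scramble_null_filter(mirna_id: str, mirna: str, utrs: dict[str, str], *,
                         n_scrambles: int = 5, seed: int = 0,
                         scheme: ScoringScheme | None = None,
                         score_threshold: float = SCORE_THRESHOLD,
                         energy_threshold: float = ENERGY_THRESHOLD,
                         ) -> list[TargetPrediction]:
    """Run the predictor for the true miRNA and n scrambled copies.

    Scrambles are uniform random permutations of the miRNA's
    nucleotides. A true-miRNA target gene also predicted for any
    scramble is discarded; survivors carry passed_scramble_null=True.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    rng = np.random.default_rng(seed)
    true_preds = predict_targets(mirna_id, mirna, utrs, scheme=scheme,
                                 score_threshold=score_threshold,
                                 energy_threshold=energy_threshold)
    null_genes: set[str] = set()
    letters = list(mirna)
    for _ in range(n_scrambles):
        perm = rng.permutation(len(letters))
        scramble = "".join(letters[i] for i in perm)
        for p in predict_targets(mirna_id, scramble, utrs, scheme=scheme,
                                 score_threshold=score_threshold,
                                 energy_threshold=energy_threshold):
            null_genes.add(p.gene)
    survivors = [p for p in true_preds if p.gene not in null_genes]
    for p in survivors:
        p.passed_scramble_null = True
    return survivors


def aggregate_targets(per_mirna: dict[str, list[TargetPrediction]],
                      mirna_fraction: float = 0.10) -> list[str]:
    """Genes targeted by at least ceil(fraction * n_mirnas) miRNAs."""
    if not 0 < mirna_fraction <= 1:
        raise ValueError("mirna_fraction must lie in (0, 1]")
    if not per_mirna:
        raise ValueError("need at least one miRNA prediction list")
    need = int(np.ceil(mirna_fraction * len(per_mirna)))
    gene_hits: dict[str, set[str]] = {}
    for mid, preds in per_mirna.items():
        for p in preds:
            if p.passed_scramble_null:
                gene_hits.setdefault(p.gene, set()).add(mid)
    return sorted(g for g, mids in gene_hits.items() if len(mids) >= need)


def predictions_to_frame(preds: list[TargetPrediction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mirna": p.mirna, "gene": p.gene, "utr_start": p.utr_start,
        "utr_end": p.utr_end, "score": p.alignment_score,
        "energy_kcal_mol": p.duplex_energy,
        "passed_scramble_null": p.passed_scramble_null,
    } for p in preds], columns=["mirna", "gene", "utr_start", "utr_end",
                                "score", "energy_kcal_mol", "passed_scramble_null"])
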