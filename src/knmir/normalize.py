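"""Count matrices, TMM normalization and expression gates.

TMM (trimmed mean of M-values) is implemented from its definition: a
reference sample is picked by the 75th-percentile rule, per-locus
log-ratios (M) and average log-abundances (A) against the reference are
doubly trimmed (30% of M, 5% of A from each tail), and the scaling
factor is the precision-weighted mean of the surviving M values, with
factors rescaled to geometric mean 1. Normalized values are
TMM-scaled counts per million.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # loci x samples
    kind: str  # "raw_counts" | "tmm_normalized"

    def __post_init__(self) -> None:
        if self.kind not in ("raw_counts", "tmm_normalized"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate locus IDs in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in expression matrix")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.kind == "raw_counts":
            arr = self.values.values
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integers")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TmmFactors:
    reference_sample: str
    factors: pd.Series  # per-sample, geometric mean 1

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


def count_matrix(read_table: pd.DataFrame, loci: pd.DataFrame) -> ExpressionMatrix:
    """featureCounts-style overlap counting.

    A read is assigned to a locus when at least 50% of the read's length
    overlaps the locus on the same strand. Loci must carry unique IDs
    and be non-overlapping per strand.
    """
    if loci["id"].duplicated().any():
        raise ValueError("duplicate locus IDs")
    samples = sorted(read_table["sample"].unique()) if len(read_table) else []
    mat = pd.DataFrame(0, index=pd.Index(list(loci["id"]), name="locus"),
                       columns=samples, dtype=np.int64)
    if not len(read_table):
        return ExpressionMatrix(mat, "raw_counts")
    for _, loc in loci.iterrows():
        sel = read_table[(read_table["chrom"] == loc["chrom"])
                         & (read_table["strand"] == loc["strand"])]
        ov = (np.minimum(sel["end"], loc["end"]) - np.maximum(sel["start"], loc["start"]))
        frac_ok = ov >= 0.5 * (sel["end"] - sel["start"])
        hits = sel[frac_ok & (ov > 0)]
        if len(hits):
            for s, n in hits["sample"].value_counts().items():
                mat.loc[loc["id"], s] = int(n)
    return ExpressionMatrix(mat, "raw_counts")


def _quantile75(x: np.ndarray) -> float:
    return float(np.quantile(x, 0.75))


def tmm_factors(counts: ExpressionMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> TmmFactors:
    """TMM scaling factors from raw counts."""
    if counts.kind != "raw_counts":
        raise ValueError("TMM factors are computed from raw counts")
    y = counts.values.values.astype(float)
    if y.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.col_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"samples with no counts: {bad}")
    f75 = np.array([_quantile75(y[:, k] / lib[k]) for k in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    for k in range(y.shape[1]):
        factors[k] = _tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref], trim_m, trim_a,
                               sample=counts.col_ids[k])
    factors = factors / math.exp(np.log(factors).mean())  # geometric mean 1
    return TmmFactors(counts.col_ids[ref],
                      pd.Series(factors, index=counts.col_ids, name="tmm_factor"))


def _tmm_pair(yk: np.ndarray, yr: np.ndarray, nk: float, nr: float,
              trim_m: float, trim_a: float, sample: str = "?") -> float:
    use = (yk > 0) & (yr > 0)
    if not use.any():
        raise ValueError(f"sample {sample!r} shares no expressed locus with the reference")
    yk, yr = yk[use], yr[use]
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    if np.allclose(m, 0):
        return 1.0
    # asymptotic (delta-method) precision of each M value
    v = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().values
    rank_a = pd.Series(a).rank().values
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = float((w * m[keep]).sum() / w.sum())
    return 2.0 ** f


def normalize(counts: ExpressionMatrix, factors: TmmFactors) -> ExpressionMatrix:
    """TMM-scaled counts per million: count / (library * factor) * 1e6."""
    missing = set(counts.col_ids) - set(factors.factors.index)
    if missing:
        raise KeyError(f"missing TMM factor for samples: {sorted(missing)}")
    lib = counts.values.sum(axis=0).astype(float)
    scale = lib * factors.factors[counts.values.columns]
    vals = counts.values / scale * 1e6
    return ExpressionMatrix(vals, "tmm_normalized")


def expression_gates(matrix: ExpressionMatrix, mode: str, *,
                     min_sum_reads: int = 10, tmm_min: float = 0.1,
                     sample_fraction: float = 0.10) -> list[str]:
    """The three expression gates used along the pipeline.

    - sum_reads: raw counts summed over samples >= min_sum_reads;
    - any_sample: normalized value > tmm_min in at least one sample;
    - fraction_of_samples: normalized value > tmm_min in at least
      ceil(sample_fraction * n_samples) samples.
    """
    v = matrix.values
    if mode == "sum_reads":
        if matrix.kind != "raw_counts":
            raise ValueError("sum_reads gate needs raw counts")
        keep = v.sum(axis=1) >= min_sum_reads
    elif mode == "any_sample":
        if matrix.kind != "tmm_normalized":
            raise ValueError("any_sample gate needs normalized values")
        keep = (v > tmm_min).any(axis=1)
    elif mode == "fraction_of_samples":
        if matrix.kind != "tmm_normalized":
            raise ValueError("fraction_of_samples gate needs normalized values")
        need = math.ceil(sample_fraction * v.shape[1])
        keep = (v > tmm_min).sum(axis=1) >= need
    else:
        raise ValueError(f"unknown gate mode {mode!r}")
    return list(v.index[keep])
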