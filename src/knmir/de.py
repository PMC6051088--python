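"""Paired tumour/normal differential expression, BH correction and
average-linkage/Pearson hierarchical clustering.

The test is a paired Student t-test on per-pair differences of the
TMM-normalized values; fold change is the mean over pairs of per-pair
tumour/normal ratios with a small pseudo-expression guarding division
by zero. An unpaired Welch variant is available behind a flag for
cohorts without pairing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

PSEUDO_EXPRESSION = 0.01


@dataclass
class DEResult:
    locus: str
    mean_fc: float
    log2fc: float
    t_stat: float
    p: float
    bh_p: float
    direction: str


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q(i) = p(i) * m / i on the ascending sort, then a cumulative
    minimum from the largest rank downward, capped at 1. NaNs pass
    through and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    q = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    out[ok] = adj
    return out


def paired_de(normalized: pd.DataFrame, pair_map: pd.DataFrame, *,
              paired: bool = True, log2: bool = False) -> pd.DataFrame:
    """Per-locus differential expression between tumour and normal.

    ``pair_map`` needs columns sample/pair/condition with exactly one
    tumour and one normal sample per pair. Returns a DataFrame with
    columns locus, mean_fc, log2fc, t, p, bh_p, direction. Loci with
    zero-variance differences get p = NaN (excluded from the BH m) with
    a warning.
    """
    piv = pair_map.pivot(index="pair", columns="condition", values="sample")
    if not {"tumour", "normal"} <= set(piv.columns) or piv.isna().any().any():
        raise ValueError("every pair needs exactly one tumour and one normal sample")
    if len(piv) < 3:
        raise ValueError("need >= 3 pairs")
    tum = normalized[piv["tumour"]].values
    nor = normalized[piv["normal"]].values  # loci x pairs
    x_t, x_n = (np.log2(tum + PSEUDO_EXPRESSION), np.log2(nor + PSEUDO_EXPRESSION)) \
        if log2 else (tum, nor)
    n = tum.shape[1]

    if paired:
        d = x_t - x_n
        sd = d.std(axis=1, ddof=1)
        mean_d = d.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / (sd / np.sqrt(n))
        df = np.full(tum.shape[0], n - 1, dtype=float)
    else:
        v_t = x_t.var(axis=1, ddof=1)
        v_n = x_n.var(axis=1, ddof=1)
        se2 = v_t / n + v_n / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (x_t.mean(axis=1) - x_n.mean(axis=1)) / np.sqrt(se2)
            df = se2 ** 2 / ((v_t / n) ** 2 / (n - 1) + (v_n / n) ** 2 / (n - 1))
    zero_var = ~np.isfinite(t)
    if zero_var.any():
        import warnings
        warnings.warn(f"{int(zero_var.sum())} loci with zero-variance differences; p set to NaN")
    # identical columns: t = 0/0 -> NaN, but mean difference 0 means p = 1
    exact_null = zero_var & np.isclose((x_t - x_n).sum(axis=1), 0)
    p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), df), np.nan)
    p[exact_null] = 1.0
    t = np.where(np.isfinite(t), t, np.where(exact_null, 0.0, np.nan))

    fc = ((tum + PSEUDO_EXPRESSION) / (nor + PSEUDO_EXPRESSION)).mean(axis=1)
    res = pd.DataFrame({
        "locus": normalized.index,
        "mean_fc": fc,
        "log2fc": np.log2(fc),
        "t": t,
        "p": p,
        "bh_p": bh_adjust(p),
        "direction": np.where(fc > 1, "up", "down"),
    })
    return res


def hier_cluster(matrix: pd.DataFrame, axis: str = "rows"
                 ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) clustering on 1 - Pearson correlation.

    Zero-variance rows are excluded with a warning. Returns the scipy
    linkage matrix and the leaf labels in dendrogram order.
    """
    data = matrix.values if axis == "rows" else matrix.values.T
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    var = data.var(axis=1)
    if (var == 0).any():
        import warnings
        warnings.warn(f"excluding {int((var == 0).sum())} zero-variance rows from clustering")
        keep = var > 0
        data = data[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    corr = np.corrcoef(data)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    return link, [labels[i] for i in order]
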