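"""Tertile grouping, Kaplan-Meier estimation and weighted log-rank tests.

The association between a miRNA's expression and patient outcome is
tested by splitting patients into expression tertiles and comparing the
top against the bottom tertile with a weighted log-rank statistic:
weights of 1 give the ordinary log-rank test, weights equal to the
pooled number at risk give the Gehan-Breslow-Wilcoxon test, which
emphasizes early survival differences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvTestResult:
    statistic: float
    p: float
    weights_kind: str
    n_per_group: dict[str, int]


def tertile_groups(expression: pd.Series) -> pd.Series:
    """Assign low/mid/high by expression tertile.

    Patients are sorted from high to low expression (ties broken by a
    stable sort on patient ID); the top floor(n/3) are "high", the
    bottom floor(n/3) are "low", and the remainder (n mod 3 extra
    patients) stay "mid" so the extreme groups remain balanced.
    """
    n = len(expression)
    if n < 6:
        raise ValueError("need >= 6 patients for tertiles")
    if expression.nunique() == 1:
        raise ValueError("all expression values equal; tertiles undefined")
    idx = expression.sort_index().index
    values = expression.loc[idx]
    order = values.sort_values(ascending=False, kind="stable").index
    third = n // 3
    groups = pd.Series("mid", index=expression.index, name="group")
    groups.loc[order[:third]] = "high"
    groups.loc[order[n - third:]] = "low"
    return groups


def km_estimate(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table (time, n_at_risk, n_events, survival) over the
    distinct event times; S(0) = 1 and S is non-increasing.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no survival records")
    if (time < 0).any():
        raise ValueError("negative survival time")
    rows = [(0.0, time.size, 0, 1.0)]
    s = 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        rows.append((float(t), n_at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def weighted_logrank(time: np.ndarray, event: np.ndarray, group: np.ndarray,
                     weights_kind: str = "gehan_breslow_wilcoxon") -> SurvTestResult:
    """Two-group weighted log-rank test.

    At each distinct event time j with pooled n_j at risk and d_j
    events, of which group 1 contributes n_1j at risk and d_1j events:

        U = sum_j w_j (d_1j - d_j n_1j / n_j)
        V = sum_j w_j^2 d_j (n_1j/n_j) (1 - n_1j/n_j) (n_j - d_j)/(n_j - 1)

    with w_j = n_j (Gehan-Breslow-Wilcoxon) or w_j = 1 (log-rank);
    terms with n_j = 1 contribute nothing to V. The statistic U^2/V is
    compared to chi-square with 1 df.
    """
    if weights_kind not in ("gehan_breslow_wilcoxon", "log_rank"):
        raise ValueError(f"unknown weights_kind {weights_kind!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    g1 = group == labels[0]
    if event.sum() == 0:
        raise ValueError("no events; weighted log-rank test undefined")
    U = 0.0
    V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_j = int(at_risk.sum())
        d_j = int(((time == t) & (event == 1)).sum())
        n_1j = int((at_risk & g1).sum())
        d_1j = int(((time == t) & (event == 1) & g1).sum())
        w = float(n_j) if weights_kind == "gehan_breslow_wilcoxon" else 1.0
        U += w * (d_1j - d_j * n_1j / n_j)
        if n_j > 1:
            V += (w ** 2) * d_j * (n_1j / n_j) * (1 - n_1j / n_j) * (n_j - d_j) / (n_j - 1)
    if V == 0:
        stat, p = 0.0, 1.0
    else:
        stat = U * U / V
        p = float(stats.chi2.sf(stat, df=1))
    return SurvTestResult(stat, p, weights_kind,
                          {str(labels[0]): int(g1.sum()), str(labels[1]): int((~g1).sum())})


def survival_scan(normalized: pd.DataFrame, annotations: pd.DataFrame, *,
                  weights_kind: str = "gehan_breslow_wilcoxon",
                  comparison: str = "high_vs_low") -> pd.DataFrame:
    """Tertile-based survival test per locus over the tumour samples.

    ``annotations`` needs columns sample/pair/condition/time_days/event;
    expression is taken from the tumour sample of each pair. The default
    comparison is top vs bottom tertile (mid excluded); ``high_vs_rest``
    keeps everyone.
    """
    tum = annotations[annotations["condition"] == "tumour"].set_index("sample")
    rows = []
    for locus in normalized.index:
        expr = normalized.loc[locus, tum.index]
        try:
            groups = tertile_groups(pd.Series(expr.values, index=tum.index))
        except ValueError:
            rows.append({"locus": locus, "statistic": np.nan, "p": np.nan,
                         "n_high": 0, "n_low": 0})
            continue
        if comparison == "high_vs_low":
            keep = groups != "mid"
        elif comparison == "high_vs_rest":
            keep = pd.Series(True, index=groups.index)
            groups = groups.replace({"mid": "low"})
        else:
            raise ValueError(f"unknown comparison {comparison!r}")
        sel = tum.loc[keep[keep].index]
        try:
            res = weighted_logrank(sel["time_days"].values, sel["event"].values,
                                   groups[keep].values, weights_kind)
            rows.append({"locus": locus, "statistic": res.statistic, "p": res.p,
                         "n_high": res.n_per_group.get("high", 0),
                         "n_low": res.n_per_group.get("low", 0)})
        except ValueError:
            rows.append({"locus": locus, "statistic": np.nan, "p": np.nan,
                         "n_high": 0, "n_low": 0})
    return pd.DataFrame(rows)
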