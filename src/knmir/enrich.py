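"""Hypergeometric pathway over-representation with BH correction.

For a query of q genes drawn from a universe of N genes of which n_p
belong to a pathway, the enrichment p-value is the upper-tail
hypergeometric probability of observing at least the actual overlap.
Pathways come from a GMT file; the universe defaults to the union of
all pathway genes. Significance is reported at BH-adjusted p <= 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass
class EnrichmentResult:
    pathway: str
    n_pathway: int
    n_overlap: int
    overlap: list[str]
    p: float
    bh_p: float


def enrich(query: set[str] | list[str], pathways: dict[str, set[str]],
           universe: set[str] | None = None,
           significance: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of query genes per pathway.

    Returns a DataFrame sorted by (bh_p, pathway) with a ``significant``
    flag at bh_p <= significance.
    """
    query = set(query)
    if not pathways:
        raise ValueError("no pathways to test")
    if universe is None:
        universe = set().union(*pathways.values())
    universe = set(universe)
    if not universe or not query:
        raise ValueError("empty universe or query")
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        overlap = sorted(query & members)
        k = len(overlap)
        # P(X >= k) drawing |query| from universe with |members| marked
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append({"pathway": name, "n_pathway": len(members), "n_overlap": k,
                     "overlap": ",".join(overlap), "p": min(p, 1.0)})
    res = pd.DataFrame(rows)
    res["bh_p"] = bh_adjust(res["p"].values)
    res["significant"] = res["bh_p"] <= significance
    return res.sort_values(["bh_p", "pathway"], ignore_index=True)
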