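"""Dinucleotide-preserving sequence shuffling (Altschul-Erickson).

A shuffle that preserves the exact dinucleotide composition of a
sequence is a random Eulerian path in the multigraph whose vertices are
the letters and whose edges are the observed dinucleotide steps. The
classic construction: pick, for every vertex except the terminal one, a
random "last exit" edge such that the chosen edges form an arborescence
into the terminal vertex; permute each vertex's remaining out-edges
uniformly; then walk the graph from the first letter, consuming the
last-exit edge of a vertex only when nothing else remains.
"""
from __future__ import annotations

import numpy as np


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    n = len(seq)
    if n < 4:
        raise ValueError("sequence too short to shuffle (< 4 nt)")
    letters = sorted(set(seq))
    if len(letters) == 1:
        return seq
    out_edges: dict[str, list[str]] = {c: [] for c in letters}
    for a, b in zip(seq, seq[1:]):
        out_edges[a].append(b)
    first, last = seq[0], seq[-1]

    # choose last-exit edges forming an arborescence toward `last`
    while True:
        last_exit = {}
        for v in letters:
            if v == last or not out_edges[v]:
                continue
            last_exit[v] = out_edges[v][rng.integers(len(out_edges[v]))]
        # check every non-terminal vertex with out-edges reaches `last`
        # by following last-exit edges
        ok = True
        for v in last_exit:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_exit:
                    ok = False
                    break
                seen.add(cur)
                cur = last_exit[cur]
            if not ok:
                break
        if ok:
            break

    shuffled_out = {}
    for v in letters:
        edges = list(out_edges[v])
        if v in last_exit:
            edges.remove(last_exit[v])
        perm = rng.permutation(len(edges))
        edges = [edges[i] for i in perm]
        if v in last_exit:
            edges.append(last_exit[v])
        shuffled_out[v] = edges

    # walk
    pos = {c: 0 for c in letters}
    walk = [first]
    cur = first
    for _ in range(n - 1):
        nxt = shuffled_out[cur][pos[cur]]
        pos[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)
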