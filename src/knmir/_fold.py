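"""Weighted base-pair maximization for hairpin scoring.

Nested-structure dynamic programming (Nussinov-style) with pair weights
G-C=3, A-U=2, G-U=1 and a minimum hairpin-loop size. The DP fill is
numba-compiled because shuffle-based p-values refold each sequence
many times.
"""
from __future__ import annotations

import numpy as np
from numba import njit

RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# pair weight lookup, indexed [code_i, code_j]
PAIR_WEIGHT = np.zeros((4, 4), dtype=np.int64)
PAIR_WEIGHT[RNA_CODE["G"], RNA_CODE["C"]] = 3
PAIR_WEIGHT[RNA_CODE["C"], RNA_CODE["G"]] = 3
PAIR_WEIGHT[RNA_CODE["A"], RNA_CODE["U"]] = 2
PAIR_WEIGHT[RNA_CODE["U"], RNA_CODE["A"]] = 2
PAIR_WEIGHT[RNA_CODE["G"], RNA_CODE["U"]] = 1
PAIR_WEIGHT[RNA_CODE["U"], RNA_CODE["G"]] = 1


def encode_rna(seq: str) -> np.ndarray:
    """Map an RNA string to integer codes; reject non-ACGU characters."""
    try:
        return np.array([RNA_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-RNA character {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _fill(codes, weights, min_loop):  # pragma: no cover - compiled
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            # j paired with some k in [i, j - min_loop - 1]
            for k in range(i, j - min_loop):
                w = weights[codes[k], codes[j]]
                if w > 0:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + w + dp[k + 1, j - 1]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def pairing_dp(codes: np.ndarray, min_loop: int = 3) -> np.ndarray:
    """Return the full DP table for the weighted pairing maximization."""
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    return _fill(codes, PAIR_WEIGHT, min_loop)


def pairing_score(codes: np.ndarray, min_loop: int = 3) -> int:
    n = codes.shape[0]
    if n == 0:
        return 0
    return int(pairing_dp(codes, min_loop)[0, n - 1])


def traceback(codes: np.ndarray, dp: np.ndarray, min_loop: int = 3) -> str:
    """Recover one optimal nested structure as a dot-bracket string.

    Deterministic tie-break: at [i, j], leaving j unpaired is preferred
    only when no pairing achieves the optimum; otherwise j pairs with
    the smallest admissible k.
    """
    n = codes.shape[0]
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = dp[i, j]
        paired = False
        for k in range(i, j - min_loop):
            w = PAIR_WEIGHT[codes[k], codes[j]]
            if w > 0:
                left = dp[i, k - 1] if k > i else 0
                if left + w + dp[k + 1, j - 1] == target:
                    struct[k] = "("
                    struct[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return "".join(struct)


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    partner = np.full(len(structure), -1, dtype=np.int64)
    opens: list[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            opens.append(idx)
        elif ch == ")":
            if not opens:
                raise ValueError("unbalanced dot-bracket string")
            k = opens.pop()
            partner[idx] = k
            partner[k] = idx
    if opens:
        raise ValueError("unbalanced dot-bracket string")
    return partner
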