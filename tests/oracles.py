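"""Brute-force reference implementations used to check the package.

These are deliberately naive (direct textbook sums, explicit
enumeration) and share no code with combipool.
"""

from __future__ import annotations

import math


def pearson_oracle(x, y) -> float:
    """Product-moment correlation via the direct-sum textbook formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    sxy = sum(a * b for a, b in zip(x, y))
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    if den == 0:
        raise ZeroDivisionError("zero variance")
    return (n * sxy - sx * sy) / den


def average_ranks(v) -> list[float]:
    """1-based ranks, ties receiving the average of their positions."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Rank, then Pearson on the average ranks."""
    return pearson_oracle(average_ranks(list(x)), average_ranks(list(y)))


def nxx_oracle(lengths, f: float) -> int:
    """Largest L among the lengths whose >=L suffix holds >= f of the total."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= f * total:
            best = L
    assert best is not None
    return best


def assign_oracle(cov, strain_ids, signature_rows, r_min=0.95, tie_eps=1e-12):
    """Independent re-derivation of the contig assignment decision.

    Recomputes every correlation with pearson_oracle, takes the strict
    maximum, and applies the threshold and tie rules.
    """
    cov = list(cov)
    if len(set(cov)) == 1:
        return "UNASSIGNED", None
    scored = []
    for sid, sig in zip(strain_ids, signature_rows):
        sig = list(sig)
        if len(set(sig)) == 1:
            continue
        scored.append((pearson_oracle(cov, sig), sid))
    if not scored:
        return "UNASSIGNED", None
    best_r = max(r for r, _ in scored)
    at_top = [sid for r, sid in scored if abs(r - best_r) <= tie_eps]
    if len(at_top) > 1 or best_r < r_min:
        return "UNASSIGNED", best_r
    return at_top[0], best_r
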