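"""Naive reference implementations used for validation.

Deliberately simple, independently written routines -- positionwise motif
rescans, exhaustive structure enumeration, per-base interval arithmetic, and
exact permutation tests -- against which the production code paths are
checked.  They share no code with the implementations they validate and are
written for clarity, not speed.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from smsite.smsite_scan import (
    BPT_CONSENSUS,
    BPT_STRINGENT,
    IUPAC_RNA,
    SS5_PATTERN,
    normalize_rna,
)

__all__ = [
    "positionwise_scan",
    "positionwise_scan_np",
    "brute_force_5ss",
    "brute_force_branchpoints",
    "enumerate_structures",
    "enumeration_max_score",
    "per_base_introns",
    "exact_rank_sum_pvalue",
]


def positionwise_scan(seq: str, pattern: str) -> list[int]:
    """Every start where the degenerate pattern matches, by direct comparison."""
    seq = normalize_rna(seq)
    classes = [IUPAC_RNA[c] for c in normalize_rna(pattern)]
    m = len(classes)
    return [
        i
        for i in range(len(seq) - m + 1)
        if all(seq[i + p] in classes[p] for p in range(m))
    ]


_B2I = {"A": 0, "C": 1, "G": 2, "U": 3}


def positionwise_scan_np(seq: str, pattern: str) -> np.ndarray:
    """Vectorized positionwise rescan (same semantics as positionwise_scan)."""
    seq = normalize_rna(seq)
    enc = np.array([_B2I.get(c, 4) for c in seq], dtype=np.int8)
    classes = [IUPAC_RNA[c] for c in normalize_rna(pattern)]
    m = len(classes)
    n = enc.size
    if n < m:
        return np.empty(0, dtype=np.int64)
    allowed = np.zeros((m, 5), dtype=bool)
    for p, cls in enumerate(classes):
        for c in cls:
            allowed[p, _B2I[c]] = True
    acc = np.ones(n - m + 1, dtype=bool)
    for p in range(m):
        acc &= allowed[p][enc[p : p + n - m + 1]]
    return np.flatnonzero(acc)


def _match_count(window: str, pattern: str) -> int:
    return sum(
        1 for c, sym in zip(window, pattern) if c in IUPAC_RNA[sym]
    )


def brute_force_5ss(seq: str, allow_bulge: bool) -> dict[int, str]:
    """Start -> kind for 5' splice-site mimics, by window-by-window checking."""
    seq = normalize_rna(seq)
    hits: dict[int, str] = {}
    m = len(SS5_PATTERN)
    for i in range(len(seq) - m + 1):
        if _match_count(seq[i : i + m], SS5_PATTERN) == m:
            hits[i] = "ss5_exact"
    if allow_bulge:
        for i in range(len(seq) - m + 1):
            if i not in hits and _match_count(seq[i : i + m], SS5_PATTERN) == m - 1:
                hits[i] = "ss5_bulge_mismatch"
        deletion_patterns = {
            SS5_PATTERN[:d] + SS5_PATTERN[d + 1 :] for d in range(m)
        }
        for i in range(len(seq) - (m - 1) + 1):
            if i in hits:
                continue
            window = seq[i : i + m - 1]
            if any(
                _match_count(window, pat) == m - 1 for pat in deletion_patterns
            ):
                hits[i] = "ss5_bulge_deletion"
    return hits


def brute_force_branchpoints(seq: str, mode: str) -> list[int]:
    pattern = {"consensus": BPT_CONSENSUS, "stringent": BPT_STRINGENT}[mode]
    return positionwise_scan(seq, pattern)


_PAIRABLE = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
}


def _pair_weight(a: str, b: str) -> int:
    return _PAIRABLE.get(frozenset((a, b)), 0)


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every valid non-crossing pairing of ``seq`` as a pair tuple.

    A pairing is valid when every pair is AU/GC/GU with at least ``min_loop``
    unpaired bases in its hairpin loop and no two pairs cross.
    """
    seq = normalize_rna(seq)
    n = len(seq)

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield ()
            return
        i, rest = positions[0], positions[1:]
        # i unpaired
        for s in rec(rest):
            yield s
        # i paired with some admissible j; non-crossing is enforced by
        # splitting the remaining positions inside/outside the pair
        for j in rest:
            if j - i - 1 < min_loop or _pair_weight(seq[i], seq[j]) == 0:
                continue
            inside = tuple(p for p in rest if i < p < j)
            outside = tuple(p for p in rest if p > j)
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield ((i, j),) + s_in + s_out

    yield from rec(tuple(range(n)))


def enumeration_max_score(seq: str, min_loop: int = 3) -> int:
    """Maximum total pair weight over exhaustive structure enumeration."""
    seq = normalize_rna(seq)
    best = 0
    for structure in enumerate_structures(seq, min_loop):
        score = sum(_pair_weight(seq[i], seq[j]) for i, j in structure)
        if score > best:
            best = score
    return best


def per_base_introns(gene) -> set[int]:
    """Intronic genomic positions of a gene by per-base set arithmetic."""
    exonic: set[int] = set()
    for t in gene.transcripts:
        for a, b in t.exons:
            exonic.update(range(a, b))
    lo, hi = gene.span()
    return set(range(lo, hi)) - exonic


def exact_rank_sum_pvalue(x, y, alternative: str = "greater") -> float:
    """Exact two-sample rank-sum p-value by full permutation enumeration.

    Enumerates every assignment of the pooled values to the two groups and
    compares Mann-Whitney U statistics (midranks for ties).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n = len(x)
    # midranks of the pooled sample (invariant under reassignment)
    order = sorted(range(len(pooled)), key=lambda k: pooled[k])
    ranks = [0.0] * len(pooled)
    k = 0
    while k < len(order):
        k2 = k
        while k2 + 1 < len(order) and pooled[order[k2 + 1]] == pooled[order[k]]:
            k2 += 1
        mid = (k + k2) / 2 + 1
        for t in range(k, k2 + 1):
            ranks[order[t]] = mid
        k = k2 + 1
    observed = sum(ranks[:n])
    count = 0
    total = 0
    eps = 1e-9
    for combo in combinations(range(len(pooled)), n):
        r1 = sum(ranks[i] for i in combo)
        if alternative == "greater":
            count += r1 >= observed - eps
        elif alternative == "less":
            count += r1 <= observed + eps
        else:
            raise ValueError(f"unknown alternative: {alternative!r}")
        total += 1
    return count / total
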