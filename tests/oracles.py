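"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations — exhaustive enumeration and
plain triple-loop dynamic programming — kept separate from the package so
the tested code path never stands in for its own reference.
"""

from __future__ import annotations


def brute_force_ssrs(
    seq: str, min_len_short: int = 12, min_units_long: int = 4
) -> set[tuple[int, int, int]]:
    """All maximal perfect tandem runs as (start, end, period) triples.

    Enumerates every (start, period), extends maximally in both
    directions, applies the period-class thresholds, keeps primitive
    motifs, and reports identical intervals once under the smallest
    period.
    """
    seq = seq.upper()
    n = len(seq)
    found: dict[tuple[int, int], int] = {}
    for p in range(1, 7):
        for start in range(n - 2 * p + 1):
            if "N" in seq[start : start + p]:
                continue
            # must be the leftmost position of its run
            if (
                start >= 1
                and seq[start - 1] != "N"
                and seq[start - 1] == seq[start - 1 + p]
            ):
                continue
            end = start + p
            while end < n and seq[end] != "N" and seq[end - p] != "N" and seq[end] == seq[end - p]:
                end += 1
            length = end - start
            if length < 2 * p:
                continue
            if p <= 3:
                if length < min_len_short:
                    continue
            elif length < min_units_long * p:
                continue
            motif = seq[start : start + p]
            primitive = all(
                not (p % d == 0 and motif == motif[:d] * (p // d))
                for d in range(1, p)
            )
            if not primitive:
                continue
            key = (start, end)
            if key not in found or p < found[key]:
                found[key] = p
    return {(a, b, p) for (a, b), p in found.items()}


def brute_force_sw(
    q: str,
    s: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Optimal affine-gap local alignment score by the full O(mn) DP.

    A gap of length L costs gap_open + L * gap_extend; N matches
    nothing.
    """
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            sub = match if (qi == s[j - 1] and qi != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def brute_force_longest_chain(
    pairs: list[tuple[int, int]], max_gap: int = 2
) -> int:
    """Length of the longest monotone chain by exhaustive enumeration.

    Only feasible for small lists; used to validate the chaining DP.
    """
    from itertools import combinations

    best = 0
    n = len(pairs)
    order = sorted(pairs)
    for r in range(n, 0, -1):
        if r <= best:
            break
        for combo in combinations(order, r):
            a = [p[0] for p in combo]
            b = [p[1] for p in combo]
            for direction in (1, -1):
                ok = True
                for (a1, b1), (a2, b2) in zip(combo, combo[1:]):
                    da = a2 - a1
                    db = direction * (b2 - b1)
                    if not (1 <= da <= max_gap + 1 and 1 <= db <= max_gap + 1):
                        ok = False
                        break
                if ok:
                    best = max(best, r)
                    break
        if best == r:
            break
    return best
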