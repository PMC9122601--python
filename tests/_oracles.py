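"""Independent reference implementations used only to check results.

These deliberately take different algorithmic routes from the package:
the alignment oracle maximises over explicit monotone match sets (O(n^4)
DP) and, at tiny sizes, enumerates every alignment path recursively; the
inverted-repeat oracle enumerates every (arm1_start, arm2_start, arm_len)
triple and applies the maximality and containment rules literally.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def matchset_local_score(a: str, b: str, matrix, gap_open: int,
                         gap_extend: int) -> float:
    """Best local alignment score as a maximum over all monotone non-empty
    sets of aligned columns; a length-k gap costs gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * m for _ in range(n)]
    for i in range(n):
        ai = a[i]
        for j in range(m):
            sub = float(matrix[ai, b[j]])
            prev = 0.0
            for i2 in range(i):
                row = M[i2]
                di = i - i2 - 1
                gap_a = gap_open + di * gap_extend if di > 0 else 0.0
                for j2 in range(j):
                    dj = j - j2 - 1
                    gap_b = gap_open + dj * gap_extend if dj > 0 else 0.0
                    cand = row[j2] - gap_a - gap_b
                    if cand > prev:
                        prev = cand
            M[i][j] = sub + prev
            if M[i][j] > best:
                best = M[i][j]
    return best


def enumerate_local_score(a: str, b: str, matrix, gap_open: int,
                          gap_extend: int) -> float:
    """Exhaustive recursion over every local alignment path (tiny n only)."""
    n, m = len(a), len(b)
    best = 0.0

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + float(matrix[a[i], b[j]]), "M")
        if i < n:
            cost = gap_extend if last == "D" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "D")
        if j < m:
            cost = gap_extend if last == "I" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "I")

    for i in range(n):
        for j in range(m):
            rec(i, j, 0.0, "")
    return best


def _pair_mismatch(x: str, y: str) -> bool:
    if x == "N" or y == "N":
        return True
    return _COMP[x] != y


def brute_force_irs(seq: str, min_arm: int, max_gap: int, max_mismatch: int,
                    length_semantics: str = "per_arm"):
    """All maximal, containment-suppressed inverted repeats by triple
    enumeration. Returns tuples
    (arm1_start, arm1_end, arm2_start, arm2_end, arm_len, spacer_len, mm)
    sorted like the scanner output.

    Mismatch counts come from per-anti-diagonal prefix sums so the triple
    loop stays O(1) per candidate; the enumeration itself is literal.
    """
    s = seq.upper()
    n = len(s)
    # prefix sums of pair mismatches along each anti-diagonal d = l + r
    diag_prefix: dict[int, list[int]] = {}
    for d in range(1, 2 * n - 2 + 1):
        lo = max(0, d - (n - 1))
        pref = [0]
        for l in range(lo, min(d, n)):
            r = d - l
            if 0 <= r < n and l < r:
                pref.append(pref[-1] + (1 if _pair_mismatch(s[l], s[r]) else 0))
            else:
                pref.append(pref[-1])
        diag_prefix[d] = (lo, pref)

    def mm(i: int, j: int, L: int) -> int:
        # pairs (i+k, j+L-1-k), all on anti-diagonal d = i + j + L - 1
        d = i + j + L - 1
        lo, pref = diag_prefix[d]
        return pref[i + L - lo] - pref[i - lo]

    def accepted(L: int, g: int) -> bool:
        if length_semantics == "per_arm":
            return L >= min_arm
        return 2 * L + g >= min_arm

    candidates = []
    for i in range(n):
        for L in range(1, n - i + 1):
            e = i + L
            for g in range(max_gap + 1):
                j = e + g
                if j + L > n:
                    break
                if mm(i, j, L) > max_mismatch:
                    continue
                # maximal: symmetric extension is (i-1, j, L+1)
                if i - 1 >= 0 and j + L + 1 <= n and \
                        mm(i - 1, j, L + 1) <= max_mismatch:
                    continue
                if accepted(L, g):
                    candidates.append((i, e, j, j + L, L, g, mm(i, j, L)))

    # literal containment rule: drop a repeat if both arms lie inside the
    # arms of a longer reported repeat with equal spacer
    kept = []
    for c in candidates:
        i1, e1, j1, f1, L1, g1, _ = c
        suppressed = any(
            o is not c and o[5] == g1 and o[4] > L1
            and o[0] <= i1 and e1 <= o[1] and o[2] <= j1 and f1 <= o[3]
            for o in candidates
        )
        if not suppressed:
            kept.append(c)
    kept.sort(key=lambda t: (t[0], -t[4], t[5]))
    return kept
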