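"""Independent reference implementations used only by tests.

These deliberately share no code with the package: primitivity by trial
division, maximal-run enumeration by direct character scanning, and repeat
alignment by a plain linear (non-wraparound) dynamic program against an
explicitly unrolled reference.
"""

from __future__ import annotations

VALID = set("ACGT")


def naive_is_primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return False
    return True


def brute_force_perfect_runs(seq: str, max_unit: int, min_length: int = 12):
    """All maximal primitive tandem runs as (start, end, unit) tuples.

    For every start and unit size, extend by direct comparison; keep only
    left-maximal runs with >= 2 copies and total length >= min_length whose
    unit is primitive (checked by trial division).  Runs never include a
    non-ACGT character.
    """
    seq = seq.upper()
    n = len(seq)
    found = set()
    for u in range(1, max_unit + 1):
        for i in range(n - 2 * u + 1):
            if any(seq[t] not in VALID for t in range(i, i + u)):
                continue
            # left-maximality: position i-1 must not continue the period
            if i > 0 and seq[i - 1] in VALID and seq[i - 1] == seq[i - 1 + u]:
                continue
            j = i + u
            while j < n and seq[j] in VALID and seq[j] == seq[j - u]:
                j += 1
            length = j - i
            if length < max(min_length, 2 * u):
                continue
            if not naive_is_primitive(seq[i : i + u]):
                continue
            found.add((i, j, seq[i : i + u]))
    return sorted(found)


def linear_repeat_align(window: str, unit: str, match=1, mismatch=-4, indel=-4):
    """Score of the best alignment of ``window`` against enough literal
    copies of ``unit``, with the reference prefix and suffix free.

    Returns (score, n_match, n_mismatch, n_indel); ties on score prefer
    more matches, then fewer indels.
    """
    window = window.upper()
    unit = unit.upper()
    m, k = len(window), len(unit)
    copies = (m // k) + 3
    ref = unit * copies
    R = len(ref)
    NEG = (-(10**9), 0, 0, 0)
    # cell = (score, n_match, -n_indel, n_mismatch); free ref prefix
    prev = [(0, 0, 0, 0)] * (R + 1)
    for i in range(1, m + 1):
        c = window[i - 1]
        cur = [NEG] * (R + 1)
        # consuming a window char against a gap (no free start for window)
        cur[0] = (prev[0][0] + indel, prev[0][1], prev[0][2] - 1, prev[0][3])
        for j in range(1, R + 1):
            hit = c == ref[j - 1]
            s = match if hit else mismatch
            p = prev[j - 1]
            best = (p[0] + s, p[1] + hit, p[2], p[3] + (not hit))
            q = prev[j]
            cand = (q[0] + indel, q[1], q[2] - 1, q[3])
            if cand > best:
                best = cand
            left = cur[j - 1]
            cand = (left[0] + indel, left[1], left[2] - 1, left[3])
            if cand > best:
                best = cand
            cur[j] = best
        prev = cur
    score, n_match, neg_ind, n_mismatch = max(prev)  # free ref suffix
    return score, n_match, n_mismatch, -neg_ind


def random_dna(rng, length: int, gc: float = 50.0) -> str:
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    return "".join(rng.choice(list("ACGT"), size=length, p=[a, g, g, a]))
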