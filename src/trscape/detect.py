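"""Tandem repeat detection: perfect runs, wraparound alignment, seed-and-extend.

Perfect detection enumerates every maximal primitive tandem run (unit sizes
1..max_unit) via vectorized self-offset matching.  Imperfect detection seeds
on short exact runs and extends both directions with a wraparound dynamic
program against indefinite repetitions of the unit; candidates below the
length or score thresholds are discarded and heavily overlapping calls are
resolved by score.

Default scoring is +1 match / -4 mismatch / -4 indel, which makes a perfect
repeat's score equal its length, so the 12-nt minimum length and the
minimum alignment score of 12 coincide on perfect repeats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import MotifError
from .motifs import canonical_class, is_primitive

_SEGMENT_RE = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class TandemRepeat:
    seq_id: str
    start: int
    end: int
    unit: str
    canonical_unit: str
    unit_length: int
    copy_number: float
    score: int
    perfect: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -4
    indel: int = -4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.indel >= 0:
            raise ValueError("mismatch and indel penalties must be negative")


@dataclass
class DetectorConfig:
    max_unit: int = 50
    min_length: int = 12
    min_score: int = 12
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    dropoff: int | None = None  # default: 2 * |mismatch|

    def __post_init__(self) -> None:
        if not 1 <= self.max_unit <= 50:
            raise ValueError("max_unit must be in 1..50")
        if self.min_length <= 0 or self.min_score <= 0:
            raise ValueError("thresholds must be positive")
        if self.dropoff is None:
            self.dropoff = 2 * abs(self.scheme.mismatch)


def _residues(seq) -> str:
    return seq if isinstance(seq, str) else seq.residues


def _match_run_spans(arr: np.ndarray, valid: np.ndarray, u: int):
    """Yield (i, j) spans of maximal runs where arr[t] == arr[t+u] for
    t in [i, j), both positions valid."""
    if arr.size <= u:
        return
    eq = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
    x = eq.view(np.int8)
    d = np.diff(x)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if x.size and x[0]:
        starts = np.concatenate(([0], starts))
    if x.size and x[-1]:
        ends = np.concatenate((ends, [x.size]))
    yield from zip(starts.tolist(), ends.tolist())


def _seq_arrays(residues: str):
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    return arr, valid


def detect_perfect(seq, max_unit: int = 50, min_length: int = 12) -> list[TandemRepeat]:
    """All maximal perfect tandem runs with a primitive unit of size
    <= max_unit, total length >= min_length and >= 2 full copies.

    Maximal means not extendable by one base on either side at the same
    period; the run never crosses a non-ACGT residue.
    """
    residues = _residues(seq).upper()
    seq_id = getattr(seq, "seq_id", "seq")
    arr, valid = _seq_arrays(residues)
    out: list[TandemRepeat] = []
    for u in range(1, max_unit + 1):
        for i, j in _match_run_spans(arr, valid, u):
            length = j - i + u
            if length < min_length or length < 2 * u:
                continue
            unit = residues[i : i + u]
            if not is_primitive(unit):
                continue
            out.append(
                TandemRepeat(
                    seq_id=seq_id,
                    start=i,
                    end=j + u,
                    unit=unit,
                    canonical_unit=canonical_class(unit),
                    unit_length=u,
                    copy_number=length / u,
                    score=length,
                    perfect=True,
                )
            )
    out.sort(key=lambda t: (t.start, t.unit_length))
    return out


# ---------------------------------------------------------------------------
# Wraparound alignment


def _check_window(window: str) -> None:
    if not window:
        raise MotifError("alignment window must be nonempty")
    if not set(window) <= set("ACGT"):
        raise MotifError("alignment window contains non-ACGT characters")


def align_against_perfect(window: str, unit: str, scheme: ScoringScheme = ScoringScheme()):
    """Optimal global alignment of ``window`` against indefinite repetitions
    of ``unit`` (wraparound dynamic programming).

    The repetition phase is free at both ends; every window character must be
    aligned.  Returns ``(score, n_match, n_mismatch, n_indel)`` at the
    optimum; ties on score prefer more matches, then fewer indels.
    """
    window = window.upper()
    unit = unit.upper()
    _check_window(window)
    if not unit or not set(unit) <= set("ACGT"):
        raise MotifError("unit must be a nonempty ACGT string")
    m, k = len(window), len(unit)
    ma, mi, ind = scheme.match, scheme.mismatch, scheme.indel

    # cell = (score, n_match, -n_indel, n_mismatch) so tuple max applies the
    # tie-break directly; unpack at the end.
    prev = [(0, 0, 0, 0)] * k
    for i in range(1, m + 1):
        c = window[i - 1]
        cur: list[tuple[int, int, int, int] | None] = [None] * k
        # Deletion moves wrap within the row; iterate to a fixed point
        # (an optimal path never deletes a full unit cycle, so this settles
        # after at most two sweeps, with a safety cap).
        for _ in range(4):
            changed = False
            for j in range(k):
                jp = j - 1 if j else k - 1
                hit = c == unit[j]
                s = ma if hit else mi
                p = prev[jp]
                best = (p[0] + s, p[1] + hit, p[2], p[3] + (not hit))
                q = prev[j]
                cand = (q[0] + ind, q[1], q[2] - 1, q[3])
                if cand > best:
                    best = cand
                left = cur[jp]
                if left is not None:
                    cand = (left[0] + ind, left[1], left[2] - 1, left[3])
                    if cand > best:
                        best = cand
                if cur[j] is None or best > cur[j]:
                    cur[j] = best
                    changed = True
            if not changed:
                break
        prev = cur  # type: ignore[assignment]
    score, n_match, neg_indel, n_mismatch = max(prev)
    return score, n_match, n_mismatch, -neg_indel


def _extension_reach(window: str, unit: str, scheme: ScoringScheme, dropoff: int):
    """Score-only wraparound DP over ``window`` rows; returns (n_consumed,
    best_score) where n_consumed is the smallest prefix length achieving the
    maximum row score.  Stops once the row maximum falls more than
    ``dropoff`` below the best seen."""
    k = len(unit)
    ma, mi, ind = scheme.match, scheme.mismatch, scheme.indel
    prev = [0] * k
    best = 0
    best_i = 0
    for i, c in enumerate(window, 1):
        cur = [-(10**9)] * k
        for _ in range(4):
            changed = False
            for j in range(k):
                jp = j - 1 if j else k - 1
                s = prev[jp] + (ma if c == unit[j] else mi)
                t = prev[j] + ind
                if t > s:
                    s = t
                t = cur[jp] + ind
                if t > s:
                    s = t
                if s > cur[j]:
                    cur[j] = s
                    changed = True
            if not changed:
                break
        prev = cur
        rowmax = max(cur)
        if rowmax > best:
            best, best_i = rowmax, i
        elif rowmax < best - dropoff:
            break
    return best_i, best


def _consensus_unit(span_seq: str, u: int) -> str:
    """Majority base per column over the full unit-length chunks of the span."""
    chunks = [span_seq[t : t + u] for t in range(0, len(span_seq) - u + 1, u)]
    if len(chunks) <= 1:
        return span_seq[:u]
    cols = []
    for pos in range(u):
        counts: dict[str, int] = {}
        for ch in chunks:
            counts[ch[pos]] = counts.get(ch[pos], 0) + 1
        cols.append(max(sorted(counts), key=counts.get))
    return "".join(cols)


def _seed_min_length(u: int) -> int:
    # >= 2 exact copies always; short units additionally need >= 8 nt to
    # bound the seed count on large sequences.
    return max(2 * u, 8) if u <= 4 else 2 * u


def detect(seq, config: DetectorConfig | None = None) -> list[TandemRepeat]:
    """Detect perfect and imperfect tandem repeats in one sequence.

    Seeds are exact runs (>= 2 copies) found per unit size; each seed is
    extended left and right by wraparound DP with a score drop-off, scored
    against the majority-consensus unit, filtered by ``min_length`` and
    ``min_score``, then de-duplicated and overlap-resolved.  A non-ACGT
    residue always terminates a repeat.
    """
    config = config or DetectorConfig()
    residues = _residues(seq).upper()
    seq_id = getattr(seq, "seq_id", "seq")
    if len(residues) < config.min_length:
        return []
    scheme = config.scheme
    candidates: dict[tuple[int, int, str], TandemRepeat] = {}

    for seg in _SEGMENT_RE.finditer(residues):
        seg_start, seg_end = seg.span()
        segment = seg.group()
        if len(segment) < min(config.min_length, 8):
            continue
        arr, valid = _seq_arrays(segment)
        seeds: list[tuple[int, int, str]] = []
        for u in range(1, config.max_unit + 1):
            min_len = _seed_min_length(u)
            for i, j in _match_run_spans(arr, valid, u):
                length = j - i + u
                if length < min_len or length < 2 * u:
                    continue
                unit = segment[i : i + u]
                if not is_primitive(unit):
                    continue
                seeds.append((i, i + length, unit))

        for s0, e0, unit in seeds:
            right_n, _ = _extension_reach(
                segment[s0:], unit, scheme, config.dropoff
            )
            left_n, _ = _extension_reach(
                segment[:e0][::-1], unit[::-1], scheme, config.dropoff
            )
            start = e0 - left_n
            end = s0 + right_n
            if end - start < config.min_length:
                continue
            span_seq = segment[start:end]
            consensus = _consensus_unit(span_seq, len(unit))
            from .motifs import primitive_unit

            consensus = primitive_unit(consensus)
            u = len(consensus)
            if (end - start) / u < 2:
                continue
            score, n_match, n_mismatch, n_indel = align_against_perfect(
                span_seq, consensus, scheme
            )
            if score < config.min_score:
                continue
            key = (seg_start + start, seg_start + end, consensus)
            if key in candidates and candidates[key].score >= score:
                continue
            candidates[key] = TandemRepeat(
                seq_id=seq_id,
                start=seg_start + start,
                end=seg_start + end,
                unit=consensus,
                canonical_unit=canonical_class(consensus),
                unit_length=u,
                copy_number=(end - start) / u,
                score=score,
                perfect=(n_mismatch == 0 and n_indel == 0),
            )

    return resolve_overlaps(list(candidates.values()))


def detect_all(records, config: DetectorConfig | None = None) -> list[TandemRepeat]:
    """Run :func:`detect` over multiple sequence records."""
    out: list[TandemRepeat] = []
    for rec in records:
        out.extend(detect(rec, config))
    return out


def resolve_overlaps(candidates: list[TandemRepeat]) -> list[TandemRepeat]:
    """Greedy non-redundancy filter.

    Candidates are ranked by score (desc), then unit length (asc), then
    start; a candidate is dropped when it overlaps an accepted repeat on the
    same sequence by >= 50% of the shorter span.
    """
    order = sorted(
        candidates, key=lambda t: (-t.score, t.unit_length, t.seq_id, t.start, t.end)
    )
    accepted: list[TandemRepeat] = []
    by_seq: dict[str, list[TandemRepeat]] = {}
    for c in order:
        ok = True
        for a in by_seq.get(c.seq_id, ()):
            ov = min(c.end, a.end) - max(c.start, a.start)
            if ov <= 0:
                continue
            shorter = min(c.end - c.start, a.end - a.start)
            if ov * 2 >= shorter:
                ok = False
                break
        if ok:
            accepted.append(c)
            by_seq.setdefault(c.seq_id, []).append(c)
    accepted.sort(key=lambda t: (t.seq_id, t.start, t.end, t.unit_length))
    return accepted
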