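"""Densities, relative densities, positional profiles and motif tables.

Density is TR base pairs per megabase of valid (A/C/G/T) sequence.  Per
region class the denominator is the union of that class's intervals, so
bases shared by several mRNAs count once; the numerator is each repeat's
overlap with the same union, also counted once.  Relative density rescales
so the whole-genome class is exactly 100.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DensityError, StatsError
from .io import SequenceRecord
from .motifs import canonical_rotation, gc_content, pair_label, reverse_complement
from .regions import GenomicRegion

N_BINS = 10


@dataclass
class DensityRecord:
    region_class: str
    total_valid_nt: int
    tr_bp: int
    density: float
    relative_density: float | None = None
    gc_percent: float | None = None


@dataclass
class ProfileRecord:
    region_class: str
    bins: list[float]
    n_trs: int

    @property
    def empty(self) -> bool:
        return self.n_trs == 0


@dataclass
class MotifFrequencyTable:
    by_unit_length: dict[int, float] = field(default_factory=dict)
    by_motif: Counter = field(default_factory=Counter)
    top_motifs: list[tuple[str, str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# interval helpers


def _union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_with_union(start: int, end: int, union: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in union:
        if s >= end:
            break
        total += max(0, min(end, e) - max(start, s))
    return total


# ---------------------------------------------------------------------------
# densities


def compute_density(
    assignments: Sequence[tuple],
    regions: Sequence[GenomicRegion],
    records: Iterable[SequenceRecord],
) -> list[DensityRecord]:
    """Per-region-class density records.

    ``assignments`` come from :func:`trscape.regions.assign_trs` over the
    same ``regions`` list; include the GENOME regions (see
    :func:`trscape.regions.genome_regions`) to obtain relative densities.
    Classes whose interval union has zero valid nucleotides raise
    :class:`DensityError`.
    """
    seqs = {r.seq_id: r.residues for r in records}
    unions: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in regions:
        unions.setdefault(r.region_class, {}).setdefault(r.seq_id, []).append(
            (r.start, r.end)
        )
    for per_seq in unions.values():
        for sid in per_seq:
            per_seq[sid] = _union(per_seq[sid])

    trs_by_class: dict[str, dict] = {}
    for t, r, _ov in assignments:
        trs_by_class.setdefault(r.region_class, {})[
            (t.seq_id, t.start, t.end, t.unit)
        ] = t

    out: list[DensityRecord] = []
    genome_density = None
    for cls, per_seq in unions.items():
        valid_nt = 0
        gc_num = 0
        gc_den = 0
        for sid, ivals in per_seq.items():
            s = seqs[sid]
            for a, b in ivals:
                sub = s[a:b]
                acgt = (
                    sub.count("A") + sub.count("C") + sub.count("G") + sub.count("T")
                )
                valid_nt += acgt
                gc_num += sub.count("G") + sub.count("C")
                gc_den += acgt
        if valid_nt == 0:
            raise DensityError(f"region class {cls}: zero valid nucleotides")
        tr_bp = 0
        for t in trs_by_class.get(cls, {}).values():
            tr_bp += _overlap_with_union(t.start, t.end, per_seq.get(t.seq_id, []))
        density = tr_bp / valid_nt * 1e6
        gc = 100.0 * gc_num / gc_den if gc_den else None
        out.append(DensityRecord(cls, valid_nt, tr_bp, density, None, gc))
        if cls == "GENOME":
            genome_density = density
    if genome_density is not None:
        for rec in out:
            rec.relative_density = relative_density(rec.density, genome_density)
    order = {c: i for i, c in enumerate(_CLASS_ORDER)}
    out.sort(key=lambda r: order.get(r.region_class, 99))
    return out


_CLASS_ORDER = (
    "GENOME",
    "UI1000",
    "UI500",
    "UI200",
    "FIVE_UTR",
    "CDS",
    "INTRON",
    "THREE_UTR",
    "DI200",
    "DI500",
    "DI1000",
    "MRNA",
)


def relative_density(region_density: float, genome_density: float) -> float:
    """Density rescaled so the whole genome is 100."""
    if genome_density <= 0:
        raise DensityError("genome density must be positive for normalization")
    return 100.0 * region_density / genome_density


# ---------------------------------------------------------------------------
# positional profiles


def _sense_offset(mid: int, region: GenomicRegion) -> int:
    if region.strand == "-":
        return (region.end - 1) - mid
    return mid - region.start


def profile_bins(trs: Sequence, region: GenomicRegion, by: str = "midpoint") -> ProfileRecord:
    """Decile occupancy of repeats along one region, 5'->3'.

    Each repeat whose anchor point (midpoint by default, start with
    ``by='start'``) lies inside the region is assigned the bin
    ``floor(10 * offset / region_length)`` (clamped to 9); bins are reported
    as percentages of the assigned repeats.
    """
    counts = [0] * N_BINS
    n = 0
    length = region.length
    for t in trs:
        if t.seq_id != region.seq_id:
            continue
        anchor = (t.start + t.end - 1) // 2 if by == "midpoint" else t.start
        if not region.start <= anchor < region.end:
            continue
        off = _sense_offset(anchor, region)
        b = min(N_BINS - 1, N_BINS * off // length)
        counts[b] += 1
        n += 1
    if n == 0:
        return ProfileRecord(region.region_class, [0.0] * N_BINS, 0)
    return ProfileRecord(region.region_class, [100.0 * c / n for c in counts], n)


def class_profiles(assignments: Sequence[tuple], by: str = "midpoint") -> dict[str, ProfileRecord]:
    """Aggregate decile profiles per region class.

    A repeat is binned in the region containing its anchor point, once per
    class, so boundary-spanning repeats are single-counted.
    """
    counts: dict[str, list[int]] = {}
    totals: dict[str, int] = {}
    seen: set[tuple] = set()
    for t, r, _ov in assignments:
        anchor = (t.start + t.end - 1) // 2 if by == "midpoint" else t.start
        if not r.start <= anchor < r.end:
            continue
        key = (r.region_class, t.seq_id, t.start, t.end, t.unit, r.start, r.end)
        if key in seen:
            continue
        seen.add(key)
        off = _sense_offset(anchor, r)
        b = min(N_BINS - 1, N_BINS * off // r.length)
        counts.setdefault(r.region_class, [0] * N_BINS)[b] += 1
        totals[r.region_class] = totals.get(r.region_class, 0) + 1
    return {
        cls: ProfileRecord(cls, [100.0 * c / totals[cls] for c in counts[cls]], totals[cls])
        for cls in counts
    }


# ---------------------------------------------------------------------------
# motif tables


def unit_size_frequency(trs: Sequence) -> MotifFrequencyTable:
    """Occurrence percentages by unit length (1-50) plus per-motif counts."""
    table = MotifFrequencyTable()
    if not trs:
        return table
    by_len: Counter = Counter(t.unit_length for t in trs)
    n = sum(by_len.values())
    table.by_unit_length = {u: 100.0 * c / n for u, c in sorted(by_len.items())}
    table.by_motif = Counter(t.canonical_unit for t in trs)
    table.top_motifs = top_motifs(trs, k=len(table.by_motif))
    return table


def top_motifs(trs: Sequence, k: int = 3) -> list[tuple[str, str, int]]:
    """Motifs ranked by occurrence count (ties alphabetical).

    Returns ``(display_label, canonical_motif, count)``; the label joins the
    reverse-complement class ("AAG/CTT") but counts remain per class.
    """
    counts = Counter(t.canonical_unit for t in trs)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(pair_label(m), m, c) for m, c in ranked[:k]]


def rc_pair_counts(trs: Sequence) -> dict[str, tuple[int, int]]:
    """Counts for each motif class and its reverse-complement class,
    keyed by the pair label."""
    counts = Counter(t.canonical_unit for t in trs)
    out: dict[str, tuple[int, int]] = {}
    for m, c in counts.items():
        rc = canonical_rotation(reverse_complement(m))
        label = pair_label(m)
        if label in out:
            continue
        out[label] = (c, counts.get(rc, 0)) if m <= rc else (counts.get(rc, 0), c)
    return out


# ---------------------------------------------------------------------------
# per-mRNA presence


def tr_presence_frequency(assignments: Sequence[tuple], models: Sequence) -> dict[str, float]:
    """Per region class, the fraction of mRNAs with at least one repeat.

    Every annotated mRNA contributes to the denominator of every class; an
    mRNA counts once per class regardless of how many repeats hit it.
    """
    if not models:
        raise StatsError("no mRNAs: presence frequency has no denominator")
    n = len({m.mrna_id for m in models})
    hit: dict[str, set[str]] = {}
    for _t, r, _ov in assignments:
        if r.mrna_id is None:
            continue
        hit.setdefault(r.region_class, set()).add(r.mrna_id)
    return {cls: len(ids) / n for cls, ids in sorted(hit.items())}


# ---------------------------------------------------------------------------
# tabular export


def densities_frame(records: Sequence[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_class": [r.region_class for r in records],
            "total_valid_nt": [r.total_valid_nt for r in records],
            "tr_bp": [r.tr_bp for r in records],
            "density_bp_per_mbp": [r.density for r in records],
            "relative_density": [r.relative_density for r in records],
            "gc_percent": [r.gc_percent for r in records],
        }
    )


def profiles_frame(profiles: dict[str, ProfileRecord]) -> pd.DataFrame:
    rows = []
    for cls, p in sorted(profiles.items()):
        rows.append(
            {"region_class": cls, "n_trs": p.n_trs}
            | {f"bin_{10 * i}_{10 * i + 9}": p.bins[i] for i in range(N_BINS)}
        )
    return pd.DataFrame(rows)


def unit_size_frame(table: MotifFrequencyTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_length": list(table.by_unit_length),
            "percent": list(table.by_unit_length.values()),
        }
    )
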