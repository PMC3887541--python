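"""Synthetic genomes with planted tandem repeats and full ground truth.

Backgrounds are iid per-base at a target GC; gene models (UTR/CDS/intron
structure on both strands) are written as standards-compliant GFF3; repeat
arrays are planted inside chosen region classes until a target density (or
an exact count) is met, optionally mutated copy-by-copy, and logged in a
truth table sufficient to recompute every alignment score.  Planted spans
are pairwise disjoint, never cross region boundaries, and their flanking
bases are adjusted so a planted array cannot be extended by chance.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import CapacityError
from .io import GeneModel, SequenceRecord, write_fasta, write_gff3
from .motifs import canonical_class, gc_content
from .regions import extract_regions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MOTIF_POOL = (
    "A",
    "C",
    "AT",
    "AC",
    "AG",
    "CG",
    "AAT",
    "AAG",
    "AGC",
    "CCG",
    "ACGT",
    "AAAT",
    "AGGC",
    "AAGAG",
    "ACGGC",
)


@dataclass
class GeneLayout:
    """Fixed-shape gene models placed at a regular pitch on each sequence."""

    n_genes_per_sequence: int = 0
    five_utr_length: int = 200
    three_utr_length: int = 200
    n_exons: int = 4
    cds_exon_length: int = 150
    intron_length: int = 150
    utr_annotated: bool = True
    margin: int = 1800  # clearance kept at sequence ends and between genes

    @property
    def gene_length(self) -> int:
        return (
            self.five_utr_length
            + self.three_utr_length
            + self.n_exons * self.cds_exon_length
            + (self.n_exons - 1) * self.intron_length
        )


@dataclass
class PlantPlan:
    """Planting target for one region class.

    Either ``density`` (bp/Mbp of the class's total length) or ``count``
    (exact number of arrays) must be set.
    """

    density: float = 0.0
    count: int | None = None
    motif_pool: tuple[str, ...] = DEFAULT_MOTIF_POOL
    min_copies: int = 4
    max_copies: int = 10
    substitution_rate: float = 0.0  # per copy
    indel_rate: float = 0.0  # per copy

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution rate must be in [0, 1)")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel rate must be in [0, 1)")


@dataclass
class SimulationSpec:
    seed: int = 0
    n_sequences: int = 1
    sequence_length: int = 100_000
    background_gc: float = 50.0
    genes: GeneLayout = field(default_factory=GeneLayout)
    planting: dict[str, PlantPlan] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genes = GeneLayout(**raw.pop("genes", {}))
        planting = {
            cls_name: PlantPlan(
                **{
                    k: tuple(v) if k == "motif_pool" else v
                    for k, v in plan.items()
                }
            )
            for cls_name, plan in raw.pop("planting", {}).items()
        }
        return cls(genes=genes, planting=planting, **raw)


@dataclass
class Mutation:
    kind: str  # 'sub' | 'del' | 'ins'
    offset: int  # offset within the (pre-mutation) array
    base: str  # new base ('sub'/'ins') or deleted base ('del')


@dataclass
class PlantedTruth:
    seq_id: str
    start: int
    end: int
    unit: str
    copies: int
    region_class: str
    mutations: list[Mutation] = field(default_factory=list)

    @property
    def planted_sequence_length(self) -> int:
        return self.end - self.start


@dataclass
class SimulationResult:
    records: list[SequenceRecord]
    models: list[GeneModel]
    truths: list[PlantedTruth]


# ---------------------------------------------------------------------------
# building blocks


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    return rng.choice(_BASES, size=length, p=[a, g, g, a])


def _make_gene(
    layout: GeneLayout, gene_start: int, strand: str, seq_id: str, idx: int
) -> GeneModel:
    f, t = layout.five_utr_length, layout.three_utr_length
    e, c, il = layout.n_exons, layout.cds_exon_length, layout.intron_length
    # left-to-right exon sizes; the 5' UTR sits at the left end on '+' and
    # at the right end on '-'
    first, last = (f, t) if strand == "+" else (t, f)
    if e == 1:
        sizes = [first + c + last]
    else:
        sizes = [first + c] + [c] * (e - 2) + [c + last]
    exons = []
    pos = gene_start
    for s in sizes:
        exons.append((pos, pos + s))
        pos += s + il
    span = (gene_start, exons[-1][1])
    if strand == "+":
        five = [(exons[0][0], exons[0][0] + f)] if f else []
        three = [(exons[-1][1] - t, exons[-1][1])] if t else []
    else:
        five = [(exons[-1][1] - f, exons[-1][1])] if f else []
        three = [(exons[0][0], exons[0][0] + t)] if t else []
    utr = five + three
    cds = []
    for s, epos in exons:
        lo, hi = s, epos
        for us, ue in utr:
            if us <= lo < ue:
                lo = ue
            if us < hi <= ue:
                hi = us
        if hi > lo:
            cds.append((lo, hi))
    return GeneModel(
        gene_id=f"gene{idx}",
        mrna_id=f"mrna{idx}",
        seq_id=seq_id,
        strand=strand,
        gene_span=span,
        exons=exons,
        cds=cds,
        five_utr=five if layout.utr_annotated else [],
        three_utr=three if layout.utr_annotated else [],
    )


def mutate_array(
    array: str,
    unit_length: int,
    substitution_rate: float,
    rng: np.random.Generator | int,
    indel_rate: float = 0.0,
) -> tuple[str, list[Mutation]]:
    """Mutate a perfect repeat array copy-by-copy.

    Per full copy: one substitution with probability ``substitution_rate``
    (uniform position, uniform over the three other bases) and one
    single-base deletion with probability ``indel_rate``.  The log records
    offsets in the pre-mutation array, sufficient to recompute the exact
    alignment score.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_copies = len(array) // unit_length
    log: list[Mutation] = []
    chars = list(array)
    deleted: set[int] = set()
    for c in range(n_copies):
        base_off = c * unit_length
        if substitution_rate and rng.random() < substitution_rate:
            pos = base_off + int(rng.integers(unit_length))
            old = chars[pos]
            alts = [b for b in "ACGT" if b != old]
            new = alts[int(rng.integers(3))]
            chars[pos] = new
            log.append(Mutation("sub", pos, new))
        if indel_rate and rng.random() < indel_rate:
            pos = base_off + int(rng.integers(unit_length))
            if pos not in deleted:
                deleted.add(pos)
                log.append(Mutation("del", pos, array[pos]))
    mutated = "".join(ch for i, ch in enumerate(chars) if i not in deleted)
    return mutated, log


def _motif_weights(pool: Sequence[str], background_gc: float) -> np.ndarray:
    # GC-matched sampling: motifs whose composition resembles the background
    # are preferred (scale 12 GC points per e-fold).
    w = np.array(
        [math.exp(-abs(gc_content(m) - background_gc) / 12.0) for m in pool]
    )
    return w / w.sum()


# ---------------------------------------------------------------------------
# generation


class _Occupancy:
    """Per-sequence blocked intervals (planted spans plus 1-nt flanks)."""

    def __init__(self) -> None:
        self._spans: list[tuple[int, int]] = []

    def is_free(self, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in self._spans)

    def add(self, start: int, end: int) -> None:
        self._spans.append((start, end))


_FLANK_GUARD = 8


def _fix_flanks(seq: np.ndarray, start: int, end: int, u: int, rng: np.random.Generator) -> None:
    """Prevent chance extension of a planted array beyond its true span.

    Every base in an 8-nt guard zone on each side is forced to break the
    array's period (seq[p] != seq[p +/- u]), so any extension accumulates
    only mismatches and stops at the drop-off."""
    for p in range(start - 1, max(-1, start - 1 - _FLANK_GUARD), -1):
        forbid = seq[p + u]
        if seq[p] == forbid:
            seq[p] = rng.choice(_BASES[_BASES != forbid])
    for p in range(end, min(seq.size, end + _FLANK_GUARD)):
        forbid = seq[p - u]
        if seq[p] == forbid:
            seq[p] = rng.choice(_BASES[_BASES != forbid])


def generate(spec: SimulationSpec, seed: int | None = None) -> SimulationResult:
    """Generate background sequences, gene annotations and planted repeats.

    Deterministic given the seed (``spec.seed`` unless overridden).  Raises
    :class:`CapacityError` when a plan cannot be met inside its region class.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    layout = spec.genes

    seq_arrays: dict[str, np.ndarray] = {}
    models: list[GeneModel] = []
    gidx = 0
    for s in range(spec.n_sequences):
        sid = f"chr{s + 1}"
        seq_arrays[sid] = _random_background(rng, spec.sequence_length, spec.background_gc)
        if layout.n_genes_per_sequence:
            pitch = spec.sequence_length // layout.n_genes_per_sequence
            if pitch < layout.gene_length + 2 * layout.margin:
                raise CapacityError(
                    "gene layout: sequence too short for the requested gene count"
                )
            for g in range(layout.n_genes_per_sequence):
                gene_start = g * pitch + layout.margin
                strand = "+" if g % 2 == 0 else "-"
                models.append(_make_gene(layout, gene_start, strand, sid, gidx))
                gidx += 1

    # region intervals per class (boundaries are never crossed by plants)
    class_intervals: dict[str, list[tuple[str, int, int]]] = {}
    for m in models:
        for r in extract_regions(m, spec.sequence_length):
            class_intervals.setdefault(r.region_class, []).append(
                (r.seq_id, r.start, r.end)
            )
    for sid in seq_arrays:
        class_intervals.setdefault("GENOME", []).append(
            (sid, 50, spec.sequence_length - 50)
        )

    occupancy = {sid: _Occupancy() for sid in seq_arrays}
    truths: list[PlantedTruth] = []

    for cls, plan in spec.planting.items():
        if plan.count is None and plan.density <= 0:
            continue
        intervals = class_intervals.get(cls)
        if not intervals:
            raise CapacityError(f"region class {cls}: no intervals to plant into")
        lengths = np.array([e - s for _, s, e in intervals], dtype=float)
        probs = lengths / lengths.sum()
        total_len = int(lengths.sum())
        target_bp = None if plan.count is not None else plan.density * total_len / 1e6
        weights = _motif_weights(plan.motif_pool, spec.background_gc)

        planted_bp = 0
        planted_n = 0
        failures = 0
        while True:
            if plan.count is not None:
                if planted_n >= plan.count:
                    break
            elif planted_bp >= target_bp:
                break
            if failures > 200:
                raise CapacityError(
                    f"region class {cls}: cannot reach planting target "
                    f"({planted_bp} bp placed of {target_bp or plan.count})"
                )
            unit = plan.motif_pool[int(rng.choice(len(plan.motif_pool), p=weights))]
            u = len(unit)
            min_c = max(plan.min_copies, 2, math.ceil(12 / u))
            max_c = max(plan.max_copies, min_c)
            copies = int(rng.integers(min_c, max_c + 1))
            array = unit * copies
            mutated, log = mutate_array(
                array, u, plan.substitution_rate, rng, plan.indel_rate
            )
            length = len(mutated)
            idx = int(rng.choice(len(intervals), p=probs))
            sid, rs, re_ = intervals[idx]
            guard = _FLANK_GUARD
            if re_ - rs < length + 2 * guard + 2:
                failures += 1
                continue
            pos = int(rng.integers(rs + guard, re_ - length - guard + 1))
            if not occupancy[sid].is_free(pos - guard, pos + length + guard):
                failures += 1
                continue
            arr = seq_arrays[sid]
            arr[pos : pos + length] = np.frombuffer(
                mutated.encode("ascii"), dtype=np.uint8
            )
            _fix_flanks(arr, pos, pos + length, u, rng)
            occupancy[sid].add(pos - guard, pos + length + guard)
            truths.append(
                PlantedTruth(sid, pos, pos + length, unit, copies, cls, log)
            )
            planted_bp += length
            planted_n += 1
            failures = 0

    records = [
        SequenceRecord(sid, arr.tobytes().decode("ascii"))
        for sid, arr in seq_arrays.items()
    ]
    truths.sort(key=lambda t: (t.seq_id, t.start))
    return SimulationResult(records, models, truths)


# ---------------------------------------------------------------------------
# truth table I/O

TRUTH_COLUMNS = ("seq_id", "start", "end", "unit", "canonical_unit", "copies", "region_class", "mutations")


def write_truth_table(truths: Sequence[PlantedTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for t in truths:
            w.writerow(
                [
                    t.seq_id,
                    t.start,
                    t.end,
                    t.unit,
                    canonical_class(t.unit),
                    t.copies,
                    t.region_class,
                    json.dumps([[m.kind, m.offset, m.base] for m in t.mutations]),
                ]
            )


def read_truth_table(path: str | Path) -> list[PlantedTruth]:
    out: list[PlantedTruth] = []
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        next(r)
        for row in r:
            out.append(
                PlantedTruth(
                    seq_id=row[0],
                    start=int(row[1]),
                    end=int(row[2]),
                    unit=row[3],
                    copies=int(row[5]),
                    region_class=row[6],
                    mutations=[Mutation(*m) for m in json.loads(row[7])],
                )
            )
    return out


def save(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "annotation.gff3",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(result.records, paths["fasta"])
    write_gff3(result.models, paths["gff3"])
    write_truth_table(result.truths, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# presets used by tests and examples


def plant_like_spec(seed: int = 0, scale: float = 1.0) -> SimulationSpec:
    """Regime with 5'-UTR and UI200 carrying the top planted densities."""
    return SimulationSpec(
        seed=seed,
        n_sequences=2,
        sequence_length=int(150_000 * scale),
        background_gc=36.0,
        genes=GeneLayout(n_genes_per_sequence=25),
        planting={
            "FIVE_UTR": PlantPlan(density=30_000),
            "UI200": PlantPlan(density=25_000),
            "CDS": PlantPlan(density=4_000),
            "INTRON": PlantPlan(density=6_000),
            "THREE_UTR": PlantPlan(density=6_000),
            "UI1000": PlantPlan(density=7_000),
            "DI200": PlantPlan(density=8_000),
        },
    )


def alga_like_spec(seed: int = 0, scale: float = 1.0) -> SimulationSpec:
    """Regime with intron and CDS carrying the top planted densities."""
    return SimulationSpec(
        seed=seed,
        n_sequences=2,
        sequence_length=int(150_000 * scale),
        background_gc=62.0,
        genes=GeneLayout(n_genes_per_sequence=25),
        planting={
            "INTRON": PlantPlan(density=32_000),
            "CDS": PlantPlan(density=24_000),
            "FIVE_UTR": PlantPlan(density=4_000),
            "THREE_UTR": PlantPlan(density=6_000),
            "UI200": PlantPlan(density=5_000),
            "DI200": PlantPlan(density=6_000),
        },
    )
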