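"""Genic/intergenic region schema.

Per mRNA: 5'-UTR, CDS, intron and 3'-UTR from the annotation, plus three
upstream (UI200/UI500/UI1000) and three downstream (DI200/DI500/DI1000)
intergenic windows tiling 1-200, 201-700 and 701-1700 nt away from the
transcript ends, in transcription orientation.  When UTRs are unannotated
the windows anchor on the gene start/end and the UTR classes are skipped.
Windows are clipped at sequence ends only — overlap with neighboring genes
is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import AnnotationError
from .io import GeneModel, SequenceRecord

REGION_CLASSES = (
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
    "GENOME",
)

INTRAGENIC_CLASSES = ("FIVE_UTR", "CDS", "INTRON", "THREE_UTR")

# (class, near offset, far offset) measured from the transcript end outward.
_WINDOW_OFFSETS = (("200", 0, 200), ("500", 200, 700), ("1000", 700, 1700))


@dataclass(frozen=True)
class GenomicRegion:
    seq_id: str
    region_class: str
    start: int
    end: int
    strand: str
    gene_id: str | None = None
    mrna_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_regions(model: GeneModel, seq_len: int) -> list[GenomicRegion]:
    """Materialize all region classes for one mRNA, clipped to [0, seq_len)."""
    out: list[GenomicRegion] = []

    def add(cls: str, start: int, end: int) -> None:
        start, end = max(0, start), min(seq_len, end)
        if end > start:
            out.append(
                GenomicRegion(
                    seq_id=model.seq_id,
                    region_class=cls,
                    start=start,
                    end=end,
                    strand=model.strand,
                    gene_id=model.gene_id,
                    mrna_id=model.mrna_id,
                )
            )

    for s, e in model.five_utr:
        add("FIVE_UTR", s, e)
    for s, e in model.cds:
        add("CDS", s, e)
    for s, e in model.three_utr:
        add("THREE_UTR", s, e)
    exons = model.exons
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise AnnotationError(f"{model.mrna_id}: exons overlap")
        if s2 > e1:
            add("INTRON", e1, s2)

    # Intergenic windows anchor on the transcript 5'/3' ends (UTR bounds when
    # annotated, gene bounds otherwise), oriented by strand.
    if model.strand == "+":
        up_anchor = min(s for s, _ in model.five_utr) if model.five_utr else model.gene_span[0]
        down_anchor = max(e for _, e in model.three_utr) if model.three_utr else model.gene_span[1]
        for tag, near, far in _WINDOW_OFFSETS:
            add(f"UI{tag}", up_anchor - far, up_anchor - near)
            add(f"DI{tag}", down_anchor + near, down_anchor + far)
    else:
        up_anchor = max(e for _, e in model.five_utr) if model.five_utr else model.gene_span[1]
        down_anchor = min(s for s, _ in model.three_utr) if model.three_utr else model.gene_span[0]
        for tag, near, far in _WINDOW_OFFSETS:
            add(f"UI{tag}", up_anchor + near, up_anchor + far)
            add(f"DI{tag}", down_anchor - far, down_anchor - near)
    return out


def extract_all_regions(
    models: Iterable[GeneModel], seq_lengths: dict[str, int]
) -> list[GenomicRegion]:
    out: list[GenomicRegion] = []
    for m in models:
        out.extend(extract_regions(m, seq_lengths[m.seq_id]))
    return out


def genome_regions(records: Iterable[SequenceRecord]) -> list[GenomicRegion]:
    """One GENOME region spanning each sequence (forward strand)."""
    return [
        GenomicRegion(r.seq_id, "GENOME", 0, len(r.residues), "+") for r in records
    ]


def mrna_regions(models: Iterable[GeneModel]) -> list[GenomicRegion]:
    """Whole-transcript spans, class MRNA, for per-mRNA presence counts."""
    out = []
    for m in models:
        lo = min(s for s, _ in m.exons)
        hi = max(e for _, e in m.exons)
        out.append(
            GenomicRegion(m.seq_id, "MRNA", lo, hi, m.strand, m.gene_id, m.mrna_id)
        )
    return out


def assign_trs(
    trs: Sequence, regions: Sequence[GenomicRegion]
) -> list[tuple]:
    """All (TR, region, overlap_bp) pairs with >= 1 bp overlap.

    A repeat crossing several regions is reported once per region with the
    clipped overlap length.
    """
    by_seq: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_seq.setdefault(r.seq_id, []).append(r)
    for rs in by_seq.values():
        rs.sort(key=lambda r: r.start)
    out: list[tuple] = []
    for t in trs:
        for r in by_seq.get(t.seq_id, ()):
            if r.start >= t.end:
                break
            ov = min(t.end, r.end) - max(t.start, r.start)
            if ov > 0:
                out.append((t, r, ov))
    return out
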