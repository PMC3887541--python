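"""Readers and writers for the formats the pipeline touches.

FASTA and the pipeline's own TSV/BED tables are parsed directly (the FASTA
reader reports the offending line on format errors, which SeqIO cannot);
GFF3 goes through :mod:`gffutils`.  All coordinates are 0-based half-open
internally and converted to 1-based inclusive only at the GFF3 boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import yaml

from .errors import AnnotationError, FastaFormatError

# DNA IUPAC alphabet; everything outside ACGT counts as invalid for length
# denominators but is carried through unchanged.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")
_VALID = frozenset("ACGT")

Interval = tuple[int, int]


@dataclass
class SequenceRecord:
    """One FASTA record; residues uppercased on construction."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def valid_length(self) -> int:
        """Number of valid nucleotides (A/C/G/T only)."""
        s = self.residues
        return s.count("A") + s.count("C") + s.count("G") + s.count("T")


@dataclass
class GeneModel:
    """One mRNA with its parent gene span and sub-features.

    All intervals are 0-based half-open assembly coordinates.  UTR lists may
    be empty (annotations without UTRs are valid).
    """

    gene_id: str
    mrna_id: str
    seq_id: str
    strand: str
    gene_span: Interval
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    five_utr: list[Interval] = field(default_factory=list)
    three_utr: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.mrna_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.mrna_id}: mRNA without exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.mrna_id}: overlapping exons")
        for name in ("cds", "five_utr", "three_utr"):
            ivals = sorted(getattr(self, name))
            setattr(self, name, ivals)
            for s, e in ivals:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise AnnotationError(
                        f"{self.mrna_id}: {name} interval [{s},{e}) outside exons"
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`FastaFormatError` naming the offending line for empty
    input, duplicate identifiers, data before the first header, or
    characters outside the DNA IUPAC alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if cur_id is not None:
            records.append(SequenceRecord(cur_id, "".join(parts)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                cur_id = header[0]
                if cur_id in seen:
                    raise FastaFormatError(f"line {lineno}: duplicate ID {cur_id!r}")
                seen.add(cur_id)
                parts = []
            else:
                if cur_id is None:
                    raise FastaFormatError(f"line {lineno}: sequence before any header")
                up = line.upper()
                bad = set(up) - IUPAC_DNA
                if bad:
                    raise FastaFormatError(
                        f"line {lineno}: non-IUPAC characters {sorted(bad)}"
                    )
                parts.append(up)
    flush()
    if not records:
        raise FastaFormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            s = rec.residues
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read canonical GFF3 into one :class:`GeneModel` per mRNA.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    Parent attributes are resolved via gffutils.  mRNAs without exons,
    children outside their mRNA span, and unknown strands raise
    :class:`AnnotationError` identifying the feature.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        mrna_id = mrna.id
        if mrna.strand not in {"+", "-"}:
            raise AnnotationError(f"{mrna_id}: unknown strand {mrna.strand!r}")
        genes = list(db.parents(mrna, featuretype="gene"))
        if genes:
            gene = genes[0]
            gene_id, gene_span = gene.id, (gene.start - 1, gene.end)
        else:
            gene_id, gene_span = mrna_id, (mrna.start - 1, mrna.end)

        def child_intervals(ftype: str) -> list[Interval]:
            out = []
            for f in db.children(mrna, featuretype=ftype):
                iv = (f.start - 1, f.end)
                if iv[0] < mrna.start - 1 or iv[1] > mrna.end:
                    raise AnnotationError(
                        f"{mrna_id}: {ftype} [{f.start},{f.end}] outside mRNA span"
                    )
                out.append(iv)
            return sorted(out)

        exons = child_intervals("exon")
        if not exons:
            raise AnnotationError(f"{mrna_id}: mRNA without exons")
        models.append(
            GeneModel(
                gene_id=gene_id,
                mrna_id=mrna_id,
                seq_id=mrna.seqid,
                strand=mrna.strand,
                gene_span=gene_span,
                exons=exons,
                cds=child_intervals("CDS"),
                five_utr=child_intervals("five_prime_UTR"),
                three_utr=child_intervals("three_prime_UTR"),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit standards-compliant GFF3 (1-based inclusive) for gene models."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, mrnas in by_gene.items():
            g = mrnas[0]
            fh.write(
                f"{g.seq_id}\ttrscape\tgene\t{g.gene_span[0] + 1}\t{g.gene_span[1]}\t.\t"
                f"{g.strand}\t.\tID={gene_id}\n"
            )
            for m in mrnas:
                lo = min(s for s, _ in m.exons)
                hi = max(e for _, e in m.exons)
                fh.write(
                    f"{m.seq_id}\ttrscape\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                    f"ID={m.mrna_id};Parent={gene_id}\n"
                )
                rows = (
                    [("exon", iv) for iv in m.exons]
                    + [("CDS", iv) for iv in m.cds]
                    + [("five_prime_UTR", iv) for iv in m.five_utr]
                    + [("three_prime_UTR", iv) for iv in m.three_utr]
                )
                for ftype, (s, e) in rows:
                    fh.write(
                        f"{m.seq_id}\ttrscape\t{ftype}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"Parent={m.mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# TR tables

TR_TABLE_COLUMNS = (
    "seq_id",
    "start",
    "end",
    "unit",
    "canonical_unit",
    "unit_len",
    "copies",
    "score",
    "perfect",
)


def write_tr_table(trs: Sequence, path: str | Path) -> None:
    """TSV with one row per tandem repeat (0-based half-open coordinates)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TR_TABLE_COLUMNS)
        for t in trs:
            w.writerow(
                [
                    t.seq_id,
                    t.start,
                    t.end,
                    t.unit,
                    t.canonical_unit,
                    t.unit_length,
                    repr(t.copy_number),
                    t.score,
                    int(t.perfect),
                ]
            )


def read_tr_table(path: str | Path) -> list:
    from .detect import TandemRepeat

    out: list[TandemRepeat] = []
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is None or tuple(header) != TR_TABLE_COLUMNS:
            raise FastaFormatError(f"{path}: not a TR table (bad header)")
        for row in r:
            out.append(
                TandemRepeat(
                    seq_id=row[0],
                    start=int(row[1]),
                    end=int(row[2]),
                    unit=row[3],
                    canonical_unit=row[4],
                    unit_length=int(row[5]),
                    copy_number=float(row[6]),
                    score=int(row[7]),
                    perfect=bool(int(row[8])),
                )
            )
    return out


def write_bed(trs: Sequence, path: str | Path) -> None:
    """BED6: name = canonical unit, score = alignment score, strand '+'."""
    with open(path, "w") as fh:
        for t in trs:
            fh.write(
                f"{t.seq_id}\t{t.start}\t{t.end}\t{t.canonical_unit}\t{t.score}\t+\n"
            )


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """BED6 for genomic regions; name = region class."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.seq_id}\t{r.start}\t{r.end}\t{r.region_class}\t0\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# Config


def load_config(path: str | Path) -> dict:
    """YAML config mirroring the CLI flags; returns {} for an empty file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FastaFormatError(f"{path}: config must be a YAML mapping")
    return data
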