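"""Readers and writers for the formats the pipeline touches.

Coordinate convention: all in-memory exon intervals are 0-based, half-open,
and listed in *transcription* order (so for a minus-strand gene the genomic
start coordinates decrease along the list).  GFF3 input (1-based, closed) is
converted at the boundary.  A light exon-table TSV dialect
(``gene_id  chromosome  strand  exon_start  exon_end`` per row, already
0-based half-open) is accepted as a simpler alternative for synthetic data.

The module also ships a small packaged fixture: the genomic characterisation
of the 14 soybean PHO1 homologues (locus, chromosome, protein length,
predicted subcellular localisation, trans-membrane segment count).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import gffutils

__all__ = [
    "GeneModel",
    "GeneRecord",
    "GeneModelError",
    "ParseError",
    "read_gene_models",
    "write_exon_table",
    "load_table1_fixture",
    "read_ct_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or cell."""


class GeneModelError(ValueError):
    """A gene model violates a structural invariant."""


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene.

    ``exons`` are 0-based half-open genomic intervals in transcription
    order.  ``cds_start_offset`` is the number of 5'-UTR bases inside the
    first exon (0 when the annotation gives no CDS features, in which case
    exons are treated as fully coding).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_offset: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: gene must have at least one exon")
        for start, end in self.exons:
            if start >= end:
                raise GeneModelError(
                    f"{self.gene_id}: empty or inverted exon interval ({start}, {end})"
                )
        ordered = sorted(self.exons)
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        genomic_starts = [s for s, _ in self.exons]
        expected = sorted(genomic_starts, reverse=(self.strand == "-"))
        if genomic_starts != expected:
            raise GeneModelError(
                f"{self.gene_id}: exons not in transcription order for strand {self.strand}"
            )
        if self.cds_start_offset < 0 or self.cds_start_offset >= self.exon_lengths()[0]:
            raise GeneModelError(f"{self.gene_id}: cds_start_offset outside first exon")

    def exon_lengths(self) -> list[int]:
        return [end - start for start, end in self.exons]

    def coding_exon_lengths(self) -> list[int]:
        lengths = self.exon_lengths()
        lengths[0] -= self.cds_start_offset
        return lengths

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class GeneRecord:
    """One row of the packaged soybean family characterisation table."""

    gene_id: str
    locus_name: str
    chromosome: int
    protein_length: int
    predicted_localizations: frozenset[str]
    tm_segments: int

    def __post_init__(self):
        if self.protein_length <= 0:
            raise ValueError(f"{self.gene_id}: protein_length must be positive")
        if self.tm_segments < 0:
            raise ValueError(f"{self.gene_id}: tm_segments must be non-negative")


# --------------------------------------------------------------- gene models


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a GFF3 file or an exon-table TSV.

    Dispatch is by extension: ``.gff``/``.gff3`` are parsed as GFF3
    (1-based closed coordinates, converted internally); anything else is
    read as the exon-table TSV dialect.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path, text)
    return _read_exon_table(path, text)


def _read_gff3(path: Path, text: str) -> list[GeneModel]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: GFF3 parse failure: {exc}") from exc

    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = list(db.children(gene, featuretype="exon", order_by="start"))
        if not exons:
            # fall back to CDS-only annotations
            exons = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not exons:
            raise ParseError(f"{path}: gene {gene.id} has no exon or CDS features")
        intervals = [(f.start - 1, f.end) for f in exons]  # to 0-based half-open
        if gene.strand == "-":
            intervals = intervals[::-1]
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        offset = 0
        if cds:
            if gene.strand == "+":
                cds_start = min(f.start - 1 for f in cds)
                offset = max(0, cds_start - intervals[0][0])
            else:
                cds_end = max(f.end for f in cds)
                offset = max(0, intervals[0][1] - cds_end)
        try:
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chromosome=gene.seqid,
                    strand=gene.strand,
                    exons=tuple(intervals),
                    cds_start_offset=offset,
                )
            )
        except GeneModelError as exc:
            raise GeneModelError(f"{path}: {exc}") from exc
    return models


_EXON_TSV_COLUMNS = ["gene_id", "chromosome", "strand", "exon_start", "exon_end"]


def _read_exon_table(path: Path, text: str) -> list[GeneModel]:
    rows: dict[str, dict] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    if reader.fieldnames is None or [c for c in _EXON_TSV_COLUMNS if c not in reader.fieldnames]:
        raise ParseError(
            f"{path}:1: exon table must have columns {', '.join(_EXON_TSV_COLUMNS)}"
        )
    for lineno, row in enumerate(reader, start=2):
        try:
            gene_id = row["gene_id"]
            start, end = int(row["exon_start"]), int(row["exon_end"])
            strand = row["strand"]
            chrom = row["chromosome"]
        except (TypeError, ValueError, KeyError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed exon row: {exc}") from exc
        entry = rows.setdefault(
            gene_id, {"chromosome": chrom, "strand": strand, "exons": []}
        )
        entry["exons"].append((start, end))
    models = []
    for gene_id, entry in rows.items():
        exons = sorted(entry["exons"], reverse=(entry["strand"] == "-"))
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=entry["chromosome"],
                strand=entry["strand"],
                exons=tuple(exons),
            )
        )
    return models


def write_exon_table(models: list[GeneModel], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_EXON_TSV_COLUMNS)
        for model in models:
            for start, end in model.exons:
                writer.writerow([model.gene_id, model.chromosome, model.strand, start, end])


# ------------------------------------------------------------------- fixture


def load_table1_fixture() -> list[GeneRecord]:
    """The 14 soybean PHO1 homologues, as characterised in the source study
    (locus names, chromosomes, protein lengths, predicted localisations and
    trans-membrane segment counts)."""
    records = []
    with resources.files("genefam.data").joinpath("table1_gmapho1.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    locus_name=row["locus_name"],
                    chromosome=int(row["chromosome"]),
                    protein_length=int(row["protein_length"]),
                    predicted_localizations=frozenset(
                        row["predicted_localizations"].split(",")
                    ),
                    tm_segments=int(row["tm_segments"]),
                )
            )
    return records


# ------------------------------------------------------------------ qPCR I/O


def read_ct_table(path):
    """Read a long-format Ct TSV (columns gene, sample, condition,
    replicate, Ct) into a :class:`genefam.qpcr.CtDataset`.

    Reference gene and calibrator sample are attached later (they are run
    configuration, not data).  Non-numeric Ct values raise
    :class:`ParseError` naming the cell; groups with fewer than two
    replicates trigger a warning.
    """
    import pandas as pd

    from .qpcr import CtDataset

    path = Path(path)
    required = ["gene", "sample", "condition", "replicate", "Ct"]
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    ct = []
    for idx, raw in frame["Ct"].items():
        try:
            ct.append(float(raw))
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric Ct value {raw!r} in data row {idx + 1}"
            ) from None
    frame = frame.assign(Ct=ct, replicate=frame["replicate"].astype(int))
    counts = frame.groupby(["gene", "sample"], sort=False).size()
    thin = counts[counts < 2]
    if len(thin):
        warnings.warn(
            f"{path}: fewer than 2 replicates for {list(thin.index)}", stacklevel=2
        )
    return CtDataset(wells=frame)
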