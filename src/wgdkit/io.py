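"""Readers and writers for the on-disk formats used across the pipeline.

Gene positions travel as BED-like TSV (``chrom  start  end  strand  gene_id``,
0-based half-open coordinates); homology hits as 12-column BLAST tabular
(outfmt 6).  Every derived table (blocks, Ks, peaks, dates, fractionation,
karyotypes) is plain TSV with a single ``#``-prefixed header line.

Inside the package the authoritative coordinate axis is ``order_index`` --
the rank of a gene along its chromosome -- and base-pair positions are kept
only for I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger("wgdkit.io")

_STRAND = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates an invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: position in bp plus its rank along the chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: int
    order_index: int


@dataclass
class GeneTable:
    """Ordered gene coordinates of one genome, grouped by chromosome.

    ``records[chrom]`` is sorted by start position and ``order_index`` is
    contiguous from 0 within each chromosome.
    """

    genomic_id: str
    records: dict[str, list[GeneRecord]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, genomic_id: str, records: Iterable[tuple[str, int, int, int, str]]
    ) -> "GeneTable":
        """Build a table from (chrom, start, end, strand, gene_id) tuples.

        Sorts per chromosome by start, assigns order_index, and rejects
        duplicate gene ids and inverted intervals.
        """
        by_chrom: dict[str, list[tuple[str, int, int, int, str]]] = {}
        seen: set[str] = set()
        for chrom, start, end, strand, gene_id in records:
            if start >= end:
                raise ValidationError(
                    f"gene {gene_id!r}: start {start} >= end {end}"
                )
            if gene_id in seen:
                raise ValidationError(f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            by_chrom.setdefault(chrom, []).append((chrom, start, end, strand, gene_id))
        table = cls(genomic_id=genomic_id)
        for chrom in sorted(by_chrom):
            rows = sorted(by_chrom[chrom], key=lambda r: (r[1], r[2], r[4]))
            table.records[chrom] = [
                GeneRecord(gene_id=g, chrom=c, start=s, end=e, strand=st, order_index=i)
                for i, (c, s, e, st, g) in enumerate(rows)
            ]
        return table

    @property
    def chromosomes(self) -> list[str]:
        return list(self.records)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.records.values())

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in self.records:
            yield from self.records[chrom]

    def order_map(self) -> dict[str, tuple[str, int]]:
        """Map gene_id -> (chrom, order_index)."""
        return {g.gene_id: (g.chrom, g.order_index) for g in self}


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST-style pairwise protein hit."""

    query_id: str
    subject_id: str
    identity_pct: float
    bitscore: float
    evalue: float


def _parse_strand(token: str, lineno: int, path: str) -> int:
    token = token.strip()
    if token in _STRAND:
        return _STRAND[token]
    if token in (".", ""):
        logger.warning("%s:%d: missing strand, defaulting to +1", path, lineno)
        return 1
    raise FormatError(f"{path}:{lineno}: unrecognised strand {token!r}")


def read_gene_table(path: str | Path, genomic_id: str | None = None) -> GeneTable:
    """Read a BED-like gene table (chrom, start, end, strand, gene_id).

    order_index is assigned by start position per chromosome, so the result
    is deterministic for a given file regardless of row order.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            chrom, start_s, end_s, strand_s, gene_id = parts[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end} for gene {gene_id!r}"
                )
            strand = _parse_strand(strand_s, lineno, str(path))
            rows.append((chrom, start, end, strand, gene_id))
    return GeneTable.from_records(genomic_id or path.stem, rows)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tstrand\tgene_id\n")
        for g in table:
            strand = "+" if g.strand > 0 else "-"
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{strand}\t{g.gene_id}\n")


def read_hits(path: str | Path, max_evalue: float = 1e-5) -> list[HomologyHit]:
    """Read 12-column BLAST tabular hits, dropping weak hits and self-hits.

    Hits with evalue > ``max_evalue`` (default 1e-5) and rows whose query
    equals the subject are removed.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                identity = float(parts[2])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score column") from exc
            if evalue < 0 or not 0 <= identity <= 100:
                raise FormatError(f"{path}:{lineno}: score out of range")
            if parts[0] == parts[1] or evalue > max_evalue:
                continue
            hits.append(
                HomologyHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity_pct=identity,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (alignment columns are filler)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t100\t0\t0\t"
                f"1\t100\t1\t100\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def write_tsv(path: str | Path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a TSV with the package's single '#'-prefixed header convention."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a '#'-headed TSV; returns (columns, rows-of-strings)."""
    columns: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if not columns:
                    columns = line.lstrip("# ").split("\t")
                continue
            rows.append(line.split("\t"))
    return columns, rows
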