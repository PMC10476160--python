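"""Hit ranking, dot-plot coordinates, and orthologous-ratio estimation.

The orthologous ratio between two genomes (the modal number of matched
chromosomal regions of one genome per region of the other) reflects their
relative polyploidy levels: a lineage with two extra whole-genome
duplications shows four matched regions per region of an unduplicated
sister (ratio 1:4).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import GeneTable, HomologyHit, write_tsv
from .synteny import CollinearBlock


class UndefinedRatioError(ValueError):
    """No collinear blocks: the orthologous ratio is undefined (not zero)."""


@dataclass(frozen=True)
class RankedHit:
    query_id: str
    subject_id: str
    identity_pct: float
    bitscore: float
    evalue: float
    rank: str  # best | second | other


@dataclass
class OrthologousRatio:
    """Modal matched-region counts per window, per chromosome and overall."""

    per_chrom_a: dict[str, int]  # modal count of B regions per window of A chrom
    per_chrom_b: dict[str, int]  # modal count of A regions per window of B chrom
    genome_wide_ratio: tuple[int, int]  # (A regions per B window, B per A window)


def rank_hits(hits: Iterable[HomologyHit]) -> list[RankedHit]:
    """Rank hits per query: best, second-best, other.

    Hits are sorted by descending bitscore with ties broken by ascending
    evalue then lexicographic subject id, so the result is a function of the
    hit multiset only.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    ranked: list[RankedHit] = []
    for query in sorted(by_query):
        ordered = sorted(
            by_query[query], key=lambda h: (-h.bitscore, h.evalue, h.subject_id)
        )
        for i, h in enumerate(ordered):
            rank = "best" if i == 0 else "second" if i == 1 else "other"
            ranked.append(
                RankedHit(
                    h.query_id, h.subject_id, h.identity_pct, h.bitscore, h.evalue, rank
                )
            )
    return ranked


def dotplot_table(
    hits: Sequence[RankedHit], table_a: GeneTable, table_b: GeneTable, path
) -> None:
    """Export dot-plot coordinates in order-index space (the block axis)."""
    map_a = table_a.order_map()
    map_b = table_b.order_map()
    rows = []
    for h in hits:
        if h.query_id in map_a and h.subject_id in map_b:
            ca, ia = map_a[h.query_id]
            cb, ib = map_b[h.subject_id]
            rows.append([ca, ia, cb, ib, h.rank])
    write_tsv(path, ["chrom_a", "a_index", "chrom_b", "b_index", "rank"], rows)


def _merge_regions(
    footprints: list[tuple[str, int, int]], merge_gap: int
) -> int:
    """Count clusters of same-chromosome footprints merged at <= merge_gap."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, lo, hi in footprints:
        per_chrom.setdefault(chrom, []).append((lo, hi))
    count = 0
    for spans in per_chrom.values():
        spans.sort()
        prev_hi = None
        for lo, hi in spans:
            if prev_hi is None or lo - prev_hi > merge_gap:
                count += 1
            prev_hi = hi if prev_hi is None else max(prev_hi, hi)
    return count


def _window_counts(
    block_spans: list[tuple[str, int, int, str, int, int]],
    table: GeneTable,
    window_genes: int,
    merge_gap: int,
) -> dict[str, list[int]]:
    """Counts of matched other-genome regions per half-overlapping window."""
    step = max(1, window_genes // 2)
    by_chrom: dict[str, list[tuple[int, int, str, int, int]]] = {}
    for ca, alo, ahi, cb, blo, bhi in block_spans:
        by_chrom.setdefault(ca, []).append((alo, ahi, cb, blo, bhi))
    counts: dict[str, list[int]] = {}
    for chrom, records in table.records.items():
        n = len(records)
        spans = by_chrom.get(chrom, [])
        chrom_counts: list[int] = []
        start = 0
        while start < n:
            end = start + window_genes
            overlapping = [
                (cb, blo, bhi)
                for alo, ahi, cb, blo, bhi in spans
                if alo < end and ahi >= start
            ]
            if overlapping:
                chrom_counts.append(_merge_regions(overlapping, merge_gap))
            start += step
        counts[chrom] = chrom_counts
    return counts


def _modal(values: list[int]) -> int | None:
    if not values:
        return None
    counter = Counter(values)
    top = max(counter.values())
    return min(v for v, c in counter.items() if c == top)


def orthologous_ratio(
    blocks_ab: Sequence[CollinearBlock],
    table_a: GeneTable,
    table_b: GeneTable,
    window_genes: int = 100,
) -> OrthologousRatio:
    """Modal matched-region counts between two genomes from their blocks.

    For each half-overlapping window of ``window_genes`` genes on one genome,
    the block footprints it overlaps on the other genome are clustered
    (same-chromosome footprints separated by <= 2 x window_genes order
    indices merge into one region) and counted; the mode is taken over
    windows covered by at least one block.  The genome-wide ratio pairs the
    two directions and is reported unreduced, matching how such ratios are
    conventionally quoted (e.g. 4:2).
    """
    if not blocks_ab:
        raise UndefinedRatioError("no collinear blocks; orthologous ratio undefined")
    merge_gap = 2 * window_genes
    spans_ab = [
        (b.chrom_a, *b.a_range, b.chrom_b, *b.b_range) for b in blocks_ab
    ]
    spans_ba = [
        (b.chrom_b, *b.b_range, b.chrom_a, *b.a_range) for b in blocks_ab
    ]
    counts_per_a = _window_counts(spans_ab, table_a, window_genes, merge_gap)
    counts_per_b = _window_counts(spans_ba, table_b, window_genes, merge_gap)
    per_chrom_a = {
        c: m for c, v in counts_per_a.items() if (m := _modal(v)) is not None
    }
    per_chrom_b = {
        c: m for c, v in counts_per_b.items() if (m := _modal(v)) is not None
    }
    all_a = [x for v in counts_per_a.values() for x in v]
    all_b = [x for v in counts_per_b.values() for x in v]
    modal_b_per_a = _modal(all_a)
    modal_a_per_b = _modal(all_b)
    if modal_b_per_a is None or modal_a_per_b is None:
        raise UndefinedRatioError("blocks cover no windows; ratio undefined")
    return OrthologousRatio(
        per_chrom_a=per_chrom_a,
        per_chrom_b=per_chrom_b,
        genome_wide_ratio=(modal_a_per_b, modal_b_per_a),
    )
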