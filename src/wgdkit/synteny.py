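"""Collinear-block detection by dynamic-programming chain extraction.

Homologous gene pairs are plotted in (order_index_A, order_index_B) space per
chromosome pair and maximal chains are found under strict monotonicity and a
gap cap on both axes.  Chain score is the number of pairs (no gap penalty);
chains are extracted greedily by descending pair count, each pair belonging
to at most one block, and chains shorter than ``min_pairs`` are discarded.
Both orientations are searched independently; there are no mixed-orientation
blocks.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .io import GeneTable, HomologyHit, ValidationError, write_tsv


class BlockPair(NamedTuple):
    a_index: int
    b_index: int
    gene_a: str
    gene_b: str
    pair_id: str


def pair_id_for(gene_a: str, gene_b: str) -> str:
    """Canonical (order-free) identifier of an unordered gene pair."""
    return "|".join(sorted((gene_a, gene_b)))


@dataclass
class CollinearBlock:
    """A chained set of homologous gene pairs with one orientation."""

    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: int
    pairs: list[BlockPair]
    median_ks: float | None = None
    ks_flagged: bool = False
    event_label: str = "unassigned"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def a_range(self) -> tuple[int, int]:
        idx = [p.a_index for p in self.pairs]
        return min(idx), max(idx)

    @property
    def b_range(self) -> tuple[int, int]:
        idx = [p.b_index for p in self.pairs]
        return min(idx), max(idx)


@dataclass(frozen=True)
class DupClass:
    gene_id: str
    dup_type: str  # wgd | tandem | proximal | dispersed | singleton


def _chain_dp(
    a_idx: np.ndarray, b_idx: np.ndarray, orientation: int, max_gap: int
) -> list[int]:
    """Longest chain under strict monotonicity and the gap cap.

    Returns indices (into the input arrays) of the best chain; ties between
    equal-length chains are broken by the smallest starting A-index (then
    smallest B-index) for determinism.
    """
    n = len(a_idx)
    if n == 0:
        return []
    b_eff = b_idx if orientation > 0 else -b_idx
    order = np.lexsort((b_eff, a_idx))
    a = a_idx[order]
    b = b_eff[order]
    length = np.ones(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for j in range(1, n):
        ok = (
            (a[:j] < a[j])
            & (a[j] - a[:j] <= max_gap)
            & (b[:j] < b[j])
            & (b[j] - b[:j] <= max_gap)
        )
        if not ok.any():
            continue
        cand = np.nonzero(ok)[0]
        best = cand[np.argmax(length[cand])]
        length[j] = length[best] + 1
        parent[j] = best
    best_len = length.max()
    # tie-break: among maximal chains pick the one whose start has the
    # smallest A-index; endpoints are compared via their chain starts
    ends = np.nonzero(length == best_len)[0]
    def _start(j: int) -> tuple[int, int]:
        while parent[j] >= 0:
            j = parent[j]
        return int(a[j]), int(b[j])
    end = min(ends, key=lambda j: (_start(int(j)), int(a[j]), int(b[j])))
    chain = []
    j = int(end)
    while j >= 0:
        chain.append(int(order[j]))
        j = int(parent[j])
    chain.reverse()
    return chain


def detect_blocks(
    hits: Iterable[HomologyHit],
    table_a: GeneTable,
    table_b: GeneTable,
    min_pairs: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain homologous gene pairs into collinear blocks.

    Output is invariant to the row order of ``hits``.  For an intra-genome
    comparison (same genomic_id on both sides) each unordered pair is used
    once and self-pairs are dropped.
    """
    map_a = table_a.order_map()
    map_b = table_b.order_map()
    intra = table_a.genomic_id == table_b.genomic_id
    missing: set[str] = set()
    pairs: set[tuple[str, int, int, str, str]] = set()
    for h in hits:
        # hit files carry both query directions; orient each hit to the
        # (table_a, table_b) axes, flipping when needed
        if h.query_id in map_a and h.subject_id in map_b:
            ga, gb = h.query_id, h.subject_id
        elif h.query_id in map_b and h.subject_id in map_a:
            ga, gb = h.subject_id, h.query_id
        else:
            if h.query_id not in map_a and h.query_id not in map_b:
                missing.add(h.query_id)
            if h.subject_id not in map_a and h.subject_id not in map_b:
                missing.add(h.subject_id)
            continue
        ca, ia = map_a[ga]
        cb, ib = map_b[gb]
        if intra:
            if ga == gb:
                continue
            if (cb, ib, gb) < (ca, ia, ga):
                ca, ia, ga, cb, ib, gb = cb, ib, gb, ca, ia, ga
        pairs.add((ca, ia, ib, ga, gb))
    if missing:
        raise ValidationError(
            "hit gene ids absent from gene tables: " + ", ".join(sorted(missing)[:10])
        )
    groups: dict[tuple[str, str], list[BlockPair]] = {}
    for ca, ia, ib, ga, gb in pairs:
        cb = map_b[gb][0]
        groups.setdefault((ca, cb), []).append(
            BlockPair(ia, ib, ga, gb, pair_id_for(ga, gb))
        )
    blocks: list[CollinearBlock] = []
    counter = 0
    for (ca, cb) in sorted(groups):
        remaining = sorted(groups[(ca, cb)])
        while len(remaining) >= min_pairs:
            a_idx = np.array([p.a_index for p in remaining])
            b_idx = np.array([p.b_index for p in remaining])
            candidates = []
            for orientation in (1, -1):
                chain = _chain_dp(a_idx, b_idx, orientation, max_gap)
                if chain:
                    candidates.append((len(chain), orientation, chain))
            if not candidates:
                break
            # longest chain first; +1 orientation preferred on exact ties
            n_best, orientation, chain = max(
                candidates, key=lambda c: (c[0], c[1])
            )
            if n_best < min_pairs:
                break
            chosen = [remaining[i] for i in chain]
            counter += 1
            blocks.append(
                CollinearBlock(
                    block_id=f"b{counter:05d}",
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    pairs=chosen,
                )
            )
            used = set(chain)
            remaining = [p for i, p in enumerate(remaining) if i not in used]
    return blocks


def block_median_ks(
    block: CollinearBlock, ks_table: Mapping[str, float]
) -> CollinearBlock:
    """Attach the median pair Ks to a block.

    Pairs lacking a Ks value are ignored; if fewer than half of the pairs
    have one, the median is left missing and the block flagged.
    """
    values = [ks_table[p.pair_id] for p in block.pairs if p.pair_id in ks_table]
    if len(values) * 2 < block.n_pairs:
        block.median_ks = None
        block.ks_flagged = True
    else:
        block.median_ks = float(statistics.median(values))
        block.ks_flagged = False
    return block


def classify_duplicates(
    blocks: Sequence[CollinearBlock],
    hits: Iterable[HomologyHit],
    table: GeneTable,
    tandem_max_gap: int = 5,
    proximal_max_gap: int = 20,
) -> list[DupClass]:
    """Classify every gene of an intra-genome comparison by duplication type.

    Priority: member of a collinear block pair -> wgd; else a hit to a gene
    on the same chromosome within ``tandem_max_gap`` order indices -> tandem;
    else within ``proximal_max_gap`` -> proximal; else any hit -> dispersed;
    else singleton.
    """
    order = table.order_map()
    in_block: set[str] = set()
    for b in blocks:
        for p in b.pairs:
            in_block.add(p.gene_a)
            in_block.add(p.gene_b)
    partners: dict[str, list[str]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        partners.setdefault(h.query_id, []).append(h.subject_id)
        partners.setdefault(h.subject_id, []).append(h.query_id)
    out: list[DupClass] = []
    for gene in table:
        gid = gene.gene_id
        if gid in in_block:
            out.append(DupClass(gid, "wgd"))
            continue
        min_gap = None
        has_hit = False
        for other in partners.get(gid, ()):
            if other not in order:
                continue
            has_hit = True
            chrom, idx = order[other]
            if chrom == gene.chrom:
                gap = abs(idx - gene.order_index)
                if min_gap is None or gap < min_gap:
                    min_gap = gap
        if min_gap is not None and min_gap <= tandem_max_gap:
            out.append(DupClass(gid, "tandem"))
        elif min_gap is not None and min_gap <= proximal_max_gap:
            out.append(DupClass(gid, "proximal"))
        elif has_hit:
            out.append(DupClass(gid, "dispersed"))
        else:
            out.append(DupClass(gid, "singleton"))
    return out


def write_blocks(blocks: Sequence[CollinearBlock], path, pairs_path=None) -> None:
    write_tsv(
        path,
        ["block_id", "chrom_a", "chrom_b", "orientation", "n_pairs", "median_ks", "event_label"],
        (
            [
                b.block_id,
                b.chrom_a,
                b.chrom_b,
                b.orientation,
                b.n_pairs,
                "NA" if b.median_ks is None else f"{b.median_ks:.6f}",
                b.event_label,
            ]
            for b in blocks
        ),
    )
    if pairs_path is not None:
        write_tsv(
            pairs_path,
            ["block_id", "gene_a", "gene_b", "a_index", "b_index", "pair_id"],
            (
                [b.block_id, p.gene_a, p.gene_b, p.a_index, p.b_index, p.pair_id]
                for b in blocks
                for p in b.pairs
            ),
        )
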