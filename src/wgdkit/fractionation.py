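"""Gene-retention profiles and the geometric model of consecutive gene loss.

After a polyploidy event, duplicated genes are removed in runs of
consecutive deletions (fractionation).  Against a less-duplicated reference
genome this leaves, per subgenome, a presence/absence profile whose runs of
absent genes follow a near-geometric length distribution
N_k = N_1 * p^(k-1), with p the run-continuation ("extension") probability.

The goodness-of-fit test is an extra-parameter F test: the one-parameter
geometric decay is compared against the two-parameter alternative
N_k = N_1 * p^(k-1) * k^b (H0: b = 0), so a LARGE p-value means the
geometric model is adequate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import f as f_dist

from .io import GeneTable, ValidationError, write_tsv
from .synteny import CollinearBlock

_RSS_TOL = 1e-10


@dataclass
class RetentionProfile:
    """Per-subgenome presence of reference genes inside block footprints."""

    reference_id: str
    # presence[subgenome][chrom] / footprint[subgenome][chrom]: bool arrays
    # over the reference gene order; only footprint positions count.
    presence: dict[str, dict[str, np.ndarray]]
    footprint: dict[str, dict[str, np.ndarray]]

    def retention_rate(self, chrom: str | None = None) -> float:
        present = covered = 0
        for sub in self.presence:
            for c, mask in self.footprint[sub].items():
                if chrom is not None and c != chrom:
                    continue
                covered += int(mask.sum())
                present += int(self.presence[sub][c][mask].sum())
        if covered == 0:
            raise ValidationError("no footprint genes for the requested scope")
        return present / covered

    def loss_rate(self, chrom: str | None = None) -> float:
        return 1.0 - self.retention_rate(chrom)


@dataclass
class GeometricLossFit:
    run_counts: dict[int, int]
    p_hat: float
    p_mle: float
    f_stat: float
    p_value: float
    excluded_runs: int = 0
    n_runs: int = 0


def retention_profile(
    ref_table: GeneTable,
    blocks: Sequence[CollinearBlock],
    subgenome_assignment: Mapping[str, str],
) -> RetentionProfile:
    """Presence/absence of reference genes per query subgenome.

    A reference gene is retained in a subgenome iff it participates in a
    block pair assigned to that subgenome; genes outside any block footprint
    of a subgenome are excluded from that subgenome's denominator.  Blocks
    missing from ``subgenome_assignment`` are ignored.
    """
    if not blocks:
        raise ValidationError("empty block set: no footprint to profile")
    n_per_chrom = {c: len(v) for c, v in ref_table.records.items()}
    presence: dict[str, dict[str, np.ndarray]] = {}
    footprint: dict[str, dict[str, np.ndarray]] = {}
    for block in blocks:
        sub = subgenome_assignment.get(block.block_id)
        if sub is None:
            continue
        if block.chrom_a not in n_per_chrom:
            raise ValidationError(
                f"block {block.block_id} references unknown chromosome {block.chrom_a!r}"
            )
        pres = presence.setdefault(sub, {})
        foot = footprint.setdefault(sub, {})
        if block.chrom_a not in pres:
            n = n_per_chrom[block.chrom_a]
            pres[block.chrom_a] = np.zeros(n, dtype=bool)
            foot[block.chrom_a] = np.zeros(n, dtype=bool)
        lo, hi = block.a_range
        foot[block.chrom_a][lo : hi + 1] = True
        for p in block.pairs:
            pres[block.chrom_a][p.a_index] = True
    if not presence:
        raise ValidationError("no block carries a subgenome assignment")
    return RetentionProfile(
        reference_id=ref_table.genomic_id, presence=presence, footprint=footprint
    )


def _runs_in_segment(present: np.ndarray) -> list[int]:
    """Lengths of absent-gene runs flanked by retained genes on both sides."""
    runs: list[int] = []
    current = 0
    seen_present = False
    for flag in present:
        if flag:
            if current and seen_present:
                runs.append(current)
            current = 0
            seen_present = True
        else:
            current += 1
    # a trailing run touches the footprint edge and is not counted
    return runs


def loss_runs(
    profile: RetentionProfile, segmental_cutoff: int = 30
) -> tuple[dict[int, int], int]:
    """Run-length counts of consecutive lost genes across all subgenomes.

    Runs are maximal stretches of absent reference genes bounded by retained
    genes within the same contiguous block footprint; runs longer than
    ``segmental_cutoff`` are treated as segmental losses and only counted in
    the excluded total.
    """
    counts: Counter[int] = Counter()
    excluded = 0
    for sub in sorted(profile.presence):
        for chrom in sorted(profile.presence[sub]):
            pres = profile.presence[sub][chrom]
            foot = profile.footprint[sub][chrom]
            # split the chromosome into contiguous footprint segments
            idx = np.flatnonzero(foot)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            segments = np.split(idx, breaks + 1)
            for seg in segments:
                for run in _runs_in_segment(pres[seg]):
                    if run > segmental_cutoff:
                        excluded += 1
                    else:
                        counts[run] += 1
    return dict(sorted(counts.items())), excluded


def fit_geometric(
    run_counts: Mapping[int, int], excluded_runs: int = 0, min_count: int = 5
) -> GeometricLossFit:
    """Fit N_k = N_1 * p^(k-1) to run-length counts.

    ``p_hat`` comes from least-squares regression of ln N_k on (k-1),
    restricted to lengths with N_k >= ``min_count`` to avoid
    log-of-small-count instability.  ``p_mle`` is the assumption-free
    closed-form estimate sum(k_i - 1) / sum(k_i) over all runs.  The F test
    compares the geometric decay with the k^b-modulated alternative; its
    tail probability is large when the geometric model is adequate.
    """
    ks = np.array(sorted(k for k, n in run_counts.items() if n > 0), dtype=float)
    if len(ks) < 3:
        raise ValidationError(
            f"need counts at >= 3 distinct run lengths, got {len(ks)}"
        )
    counts = np.array([run_counts[int(k)] for k in ks], dtype=float)
    total_runs = counts.sum()
    p_mle = float(((ks - 1) * counts).sum() / (ks * counts).sum())

    usable = counts >= min_count
    ku, cu = ks[usable], counts[usable]
    if len(ku) < 3:
        raise ValidationError(
            f"need >= 3 run lengths with count >= {min_count} for the regression"
        )
    y = np.log(cu)
    x1 = np.column_stack([np.ones_like(ku), ku - 1.0])
    beta1, *_ = np.linalg.lstsq(x1, y, rcond=None)
    rss1 = float(((y - x1 @ beta1) ** 2).sum())
    p_hat = float(np.exp(beta1[1]))

    x2 = np.column_stack([np.ones_like(ku), ku - 1.0, np.log(ku)])
    beta2, *_ = np.linalg.lstsq(x2, y, rcond=None)
    rss2 = float(((y - x2 @ beta2) ** 2).sum())

    dof = len(ku) - 3
    if rss1 <= _RSS_TOL:
        f_stat, p_value = 0.0, 1.0  # geometric decay fits exactly
    elif rss2 <= _RSS_TOL or dof < 1:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (rss1 - rss2) / (rss2 / dof)
        p_value = float(f_dist.sf(f_stat, 1, dof))
    return GeometricLossFit(
        run_counts=dict(sorted((int(k), int(n)) for k, n in run_counts.items())),
        p_hat=p_hat,
        p_mle=p_mle,
        f_stat=float(f_stat),
        p_value=float(p_value),
        excluded_runs=excluded_runs,
        n_runs=int(total_runs),
    )


def write_fractionation(
    profile: RetentionProfile,
    fit: GeometricLossFit | None,
    prefix,
) -> None:
    """Write per-chromosome retention, run counts, and the fit summary."""
    chroms = sorted({c for sub in profile.footprint.values() for c in sub})
    rows = []
    for chrom in chroms:
        try:
            rows.append([chrom, f"{profile.retention_rate(chrom):.6f}", f"{profile.loss_rate(chrom):.6f}"])
        except ValidationError:
            continue
    rows.append(["genome_wide", f"{profile.retention_rate():.6f}", f"{profile.loss_rate():.6f}"])
    write_tsv(f"{prefix}.retention.tsv", ["chrom", "retention_rate", "loss_rate"], rows)
    if fit is not None:
        write_tsv(
            f"{prefix}.runs.tsv",
            ["run_length", "count"],
            ([k, n] for k, n in fit.run_counts.items()),
        )
        write_tsv(
            f"{prefix}.fit.tsv",
            ["p_hat", "p_mle", "f_stat", "p_value", "excluded_runs", "n_runs"],
            [[f"{fit.p_hat:.6f}", f"{fit.p_mle:.6f}", f"{fit.f_stat:.6g}", f"{fit.p_value:.6g}", fit.excluded_runs, fit.n_runs]],
        )
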