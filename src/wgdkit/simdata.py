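"""Synthetic genome-evolution generator with full ground truth.

The generator starts from an ancestral gene order shared by all lineages,
lets the lineages diverge at a configured synonymous distance, and plays a
per-lineage script of events, each stamped with a Ks age (the simulation
clock; calendar years only enter downstream through an explicit
calibration):

* ``WGD`` / ``WGT`` duplicate (triplicate) every chromosome and are followed
  by geometric segment-wise gene loss: each retained duplicate gene
  independently initiates a loss run on its homoeolog with probability
  ``loss_initiation_rate`` and the run extends gene by gene with
  continuation probability ``loss_extension_p``.  A run never deletes the
  last surviving copy of a gene, so fractionation removes duplicates only.
* ``EEJ`` / ``NCF`` / ``XO`` / ``IV`` rearrange chromosomes without creating
  or destroying genes.

True pairwise Ks between two gene copies is the age of their most recent
shared duplication event (or the lineage divergence for cross-lineage
pairs).  Homology hit bitscores decrease monotonically with true Ks, so the
true ortholog / most recent paralog is always the best hit.  In table mode,
observed pair Ks is the true Ks plus Gaussian noise truncated at zero; in
sequence mode, codon sequences accrue Poisson-distributed synonymous
substitutions so that NG86 recovers the true Ks in expectation (the codon
alphabet is restricted to amino acids with fourfold-degenerate third
positions, which makes the synonymous process exactly Jukes-Cantor and the
estimator unbiased).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GeneTable, HomologyHit, ValidationError, write_tsv
from .synteny import pair_id_for

DUP_EVENTS = {"WGD": 2, "WGT": 3}
REARRANGEMENTS = {"EEJ", "NCF", "XO", "IV"}

#: Codons whose third position is fourfold degenerate and whose amino acids
#: (V, S, P, T, A, G) admit no synonymous one-step change at the first or
#: second position; under this alphabet every codon carries exactly one
#: synonymous site and the synonymous substitution process is four-state
#: Jukes-Cantor, which the NG86 + JC estimator inverts without bias.
FOURFOLD_CODONS = tuple(
    prefix + base
    for prefix in ("GT", "TC", "CC", "AC", "GC", "GG")
    for base in "ACGT"
)

_BITSCORE_S0 = 500.0
_BITSCORE_LAMBDA = 1.0


@dataclass
class SimConfig:
    """Study conditions of a simulation run.

    Defaults emulate the scenario the analysis is built for: an unduplicated
    reference lineage against a lineage that underwent two sequential
    whole-genome duplications (Ks ages 0.66 and 0.30), with geometric
    fractionation after each.  ``loss_extension_p`` defaults to the
    real-data extension parameter 0.28; the initiation rate is a free
    parameter of the model (0.2 by default).
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 500
    lineage_scripts: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {"A": [], "B": [("WGD", 0.66), ("WGD", 0.30)]}
    )
    divergence_ks: float = 1.90
    loss_extension_p: float = 0.28
    loss_initiation_rate: float = 0.2
    ks_noise_sd: float = 0.05
    sequence_mode: str = "table"  # table | sequence
    codons_per_gene: int = 150
    ka_ks_ratio: float = 0.0
    n_tandem_arrays: int = 0
    tandem_array_size: int = 3
    tandem_ks: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.loss_extension_p < 1:
            raise ValidationError("loss_extension_p must lie in [0, 1)")
        if not 0 <= self.loss_initiation_rate <= 1:
            raise ValidationError("loss_initiation_rate must lie in [0, 1]")
        if self.divergence_ks < 0:
            raise ValidationError("divergence_ks must be >= 0")
        if self.ks_noise_sd < 0:
            raise ValidationError("ks_noise_sd must be >= 0")
        if self.sequence_mode not in ("table", "sequence"):
            raise ValidationError("sequence_mode must be 'table' or 'sequence'")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValidationError("genome dimensions must be positive")
        for lineage, script in self.lineage_scripts.items():
            last = math.inf
            for kind, age in script:
                if kind not in DUP_EVENTS and kind not in REARRANGEMENTS:
                    raise ValidationError(
                        f"lineage {lineage!r}: unknown event kind {kind!r}"
                    )
                if age < 0:
                    raise ValidationError(f"lineage {lineage!r}: negative event age")
                if age > last:
                    raise ValidationError(
                        f"lineage {lineage!r}: event ages must be non-increasing"
                    )
                if len(self.lineage_scripts) > 1 and age > self.divergence_ks:
                    raise ValidationError(
                        f"lineage {lineage!r}: event age {age} predates the "
                        f"lineage divergence ({self.divergence_ks})"
                    )
                last = age


@dataclass
class SimEvent:
    lineage: str
    kind: str
    age: float
    detail: str = ""


@dataclass
class SimTruth:
    """Ground truth: events, true pair Ks, loss runs, ancestral identity."""

    true_events: list[SimEvent]
    true_pair_ks: dict[str, float]  # pair_id -> Ks
    loss_runs: dict[str, list[int]]  # per duplication event label
    ancestral_identity: dict[str, tuple[str, str]]  # gene -> (anc gene, anc chrom)
    subgenome: dict[str, str]  # gene -> copy-path label, e.g. "B:ab"


@dataclass
class SimResult:
    tables: dict[str, GeneTable]
    hits: dict[tuple[str, str], list[HomologyHit]]
    observed_ks: dict[str, float] | None
    cds: dict[str, str] | None
    truth: SimTruth


class _Gene:
    __slots__ = ("anc", "anc_chrom", "path", "orientation", "tandem_of")

    def __init__(self, anc, anc_chrom, path=(), orientation=1, tandem_of=None):
        self.anc = anc
        self.anc_chrom = anc_chrom
        self.path = path
        self.orientation = orientation
        self.tandem_of = tandem_of


def _gene_id(lineage: str, gene: _Gene) -> str:
    suffix = "".join(gene.path)
    gid = f"{lineage}_{gene.anc}"
    if suffix:
        gid += f"_{suffix}"
    if gene.tandem_of is not None:
        gid += f"_t{gene.tandem_of[1]}"
    return gid


def sample_loss_run_lengths(
    n: int, extension_p: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` run lengths from the geometric loss-run model.

    P(L = k) = extension_p^(k-1) * (1 - extension_p), k >= 1.
    """
    if not 0 <= extension_p < 1:
        raise ValidationError("extension_p must lie in [0, 1)")
    return rng.geometric(1.0 - extension_p, size=n)


class _Lineage:
    def __init__(self, name: str, chroms: list[tuple[str, list[_Gene]]]):
        self.name = name
        self.chroms = chroms  # list of (chrom name, ordered genes)
        self.dup_ages: list[float] = []
        self.copy_count: dict[str, int] = {}
        for _, genes in chroms:
            for g in genes:
                self.copy_count[g.anc] = self.copy_count.get(g.anc, 0) + 1


def _apply_duplication(
    lin: _Lineage,
    kind: str,
    age: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: SimTruth,
) -> None:
    n_copies = DUP_EVENTS[kind]
    letters = "abc"[:n_copies]
    lin.dup_ages.append(age)
    groups: list[list[tuple[str, list[_Gene]]]] = []
    new_chroms: list[tuple[str, list[_Gene]]] = []
    for name, genes in lin.chroms:
        group = []
        for letter in letters:
            copy_genes = [
                _Gene(g.anc, g.anc_chrom, g.path + (letter,), g.orientation, g.tandem_of)
                for g in genes
            ]
            group.append((f"{name}{letter}", copy_genes))
        groups.append(group)
        new_chroms.extend(group)
    lin.chroms = new_chroms
    for anc in lin.copy_count:
        lin.copy_count[anc] *= n_copies

    event_label = f"{lin.name}:{kind}@{age:g}"
    runs: list[int] = []
    # geometric segment loss between the fresh homoeologous copies
    for group in groups:
        deleted = [np.zeros(len(genes), dtype=bool) for _, genes in group]
        order = list(range(len(group)))
        for src_i in order:
            _, src_genes = group[src_i]
            targets = [i for i in order if i != src_i]
            for pos in range(len(src_genes)):
                if deleted[src_i][pos]:
                    continue  # only retained genes initiate runs
                if rng.random() >= cfg.loss_initiation_rate:
                    continue
                dst_i = targets[rng.integers(len(targets))] if len(targets) > 1 else targets[0]
                dst_genes = group[dst_i][1]
                j = pos
                steps = 0
                while j < len(dst_genes):
                    g = dst_genes[j]
                    if not deleted[dst_i][j] and lin.copy_count[g.anc] <= 1:
                        break  # unconditional retention of the last copy
                    if not deleted[dst_i][j]:
                        deleted[dst_i][j] = True
                        lin.copy_count[g.anc] -= 1
                    steps += 1
                    j += 1
                    if rng.random() >= cfg.loss_extension_p:
                        break
                # the generated run length (geometric draw, truncated only
                # at a chromosome end or a protected last copy); overlapping
                # runs merge in the genome but are recorded individually
                if steps:
                    runs.append(steps)
        for copy_i, (name, genes) in enumerate(group):
            mask = deleted[copy_i]
            kept = [g for g, d in zip(genes, mask) if not d]
            for idx, (cname, cgenes) in enumerate(lin.chroms):
                if cname == name:
                    lin.chroms[idx] = (cname, kept)
                    break
    truth.loss_runs[event_label] = runs
    truth.true_events.append(SimEvent(lin.name, kind, age, f"{n_copies}x"))


def _apply_rearrangement(
    lin: _Lineage, kind: str, age: float, rng: np.random.Generator, truth: SimTruth
) -> None:
    chroms = lin.chroms
    if kind == "EEJ" and len(chroms) >= 2:
        i, j = sorted(rng.choice(len(chroms), size=2, replace=False))
        name_i, genes_i = chroms[i]
        name_j, genes_j = chroms[j]
        chroms[i] = (name_i, genes_i + genes_j)
        del chroms[j]
        detail = f"{name_i}+{name_j}"
    elif kind == "NCF" and len(chroms) >= 2:
        i, j = sorted(rng.choice(len(chroms), size=2, replace=False))
        host, genes_h = chroms[i]
        donor, genes_d = chroms[j]
        mid = len(genes_h) // 2
        chroms[i] = (host, genes_h[:mid] + genes_d + genes_h[mid:])
        del chroms[j]
        detail = f"{host}<{donor}"
    elif kind == "XO" and len(chroms) >= 2:
        i, j = sorted(rng.choice(len(chroms), size=2, replace=False))
        name_i, genes_i = chroms[i]
        name_j, genes_j = chroms[j]
        if len(genes_i) < 2 or len(genes_j) < 2:
            detail = "skipped (chromosome too short)"
        else:
            cut_i = int(rng.integers(1, len(genes_i)))
            cut_j = int(rng.integers(1, len(genes_j)))
            chroms[i] = (name_i, genes_i[:cut_i] + genes_j[cut_j:])
            chroms[j] = (name_j, genes_j[:cut_j] + genes_i[cut_i:])
            detail = f"{name_i}@{cut_i}x{name_j}@{cut_j}"
    elif kind == "IV":
        i = int(rng.integers(len(chroms)))
        name, genes = chroms[i]
        if len(genes) < 2:
            detail = "skipped (chromosome too short)"
        else:
            lo = int(rng.integers(0, len(genes) - 1))
            hi = int(rng.integers(lo + 1, len(genes)))
            mid = [
                _Gene(g.anc, g.anc_chrom, g.path, -g.orientation, g.tandem_of)
                for g in reversed(genes[lo : hi + 1])
            ]
            chroms[i] = (name, genes[:lo] + mid + genes[hi + 1 :])
            detail = f"{name}@{lo}-{hi}"
    else:
        detail = "skipped (too few chromosomes)"
    truth.true_events.append(SimEvent(lin.name, kind, age, detail))


def _true_ks(
    lineage_a: str,
    gene_a: _Gene,
    lineage_b: str,
    gene_b: _Gene,
    dup_ages: dict[str, list[float]],
    cfg: SimConfig,
) -> float:
    if lineage_a != lineage_b:
        return cfg.divergence_ks
    if gene_a.tandem_of is not None or gene_b.tandem_of is not None:
        src_a = gene_a.tandem_of[0] if gene_a.tandem_of else gene_a.path
        src_b = gene_b.tandem_of[0] if gene_b.tandem_of else gene_b.path
        if src_a == src_b:
            return cfg.tandem_ks
        gene_a = _Gene(gene_a.anc, gene_a.anc_chrom, src_a)
        gene_b = _Gene(gene_b.anc, gene_b.anc_chrom, src_b)
    ages = dup_ages[lineage_a]
    for idx, (la, lb) in enumerate(zip(gene_a.path, gene_b.path)):
        if la != lb:
            return ages[idx]
    raise ValidationError("identical copy paths for two distinct genes")


def _evolve_seq(
    codons: list[str], d: float, cfg: SimConfig, rng: np.random.Generator
) -> list[str]:
    """Accrue ``d`` synonymous substitutions per synonymous site (JC)."""
    codons = list(codons)
    n = len(codons)
    n_events = int(rng.poisson(d * n))  # one synonymous site per codon
    for _ in range(n_events):
        pos = int(rng.integers(n))
        codon = codons[pos]
        alternatives = [codon[:2] + b for b in "ACGT" if b != codon[2]]
        codons[pos] = alternatives[int(rng.integers(3))]
    if cfg.ka_ks_ratio > 0:
        n_nonsyn = int(rng.poisson(cfg.ka_ks_ratio * d * 2 * n))
        prefixes = {c[:2] for c in FOURFOLD_CODONS}
        for _ in range(n_nonsyn):
            pos = int(rng.integers(n))
            codon = codons[pos]
            for _attempt in range(10):
                p = int(rng.integers(2))
                b = "ACGT"[int(rng.integers(4))]
                if b == codon[p]:
                    continue
                new = codon[:p] + b + codon[p + 1 :]
                if new[:2] in prefixes:  # stay fourfold-degenerate, never a stop
                    codons[pos] = new
                    break
    return codons


def _leaf_sequences(
    root: list[str],
    t_now: float,
    events: list[tuple[str, float]],
    needed: set[tuple],
    cfg: SimConfig,
    rng: np.random.Generator,
    prefix: tuple = (),
) -> dict[tuple, list[str]]:
    """Evolve the copy tree of one ancestral gene down to its leaf paths."""
    if not events:
        if prefix in needed:
            return {prefix: _evolve_seq(root, t_now / 2.0, cfg, rng)}
        return {}
    kind, age = events[0]
    trunk = _evolve_seq(root, (t_now - age) / 2.0, cfg, rng)
    out: dict[tuple, list[str]] = {}
    for letter in "abc"[: DUP_EVENTS[kind]]:
        child_prefix = prefix + (letter,)
        if any(p[: len(child_prefix)] == child_prefix for p in needed):
            out.update(
                _leaf_sequences(
                    trunk, age, events[1:], needed, cfg, rng, child_prefix
                )
            )
    return out


def simulate(config: SimConfig) -> SimResult:
    """Run the generator; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lineages = sorted(config.lineage_scripts)
    anc_chroms = [
        (
            f"chr{c + 1}",
            [
                _Gene(f"g{c + 1}_{i}", f"chr{c + 1}")
                for i in range(config.genes_per_chromosome)
            ],
        )
        for c in range(config.n_chromosomes)
    ]
    truth = SimTruth(
        true_events=[], true_pair_ks={}, loss_runs={}, ancestral_identity={}, subgenome={}
    )
    lins: dict[str, _Lineage] = {}
    for name in lineages:
        chroms = [
            (f"{name}_{cname}", [
                _Gene(g.anc, g.anc_chrom, (), 1, None) for g in genes
            ])
            for cname, genes in anc_chroms
        ]
        lin = _Lineage(name, chroms)
        for kind, age in config.lineage_scripts[name]:
            if kind in DUP_EVENTS:
                _apply_duplication(lin, kind, age, config, rng, truth)
            else:
                _apply_rearrangement(lin, kind, age, rng, truth)
        lins[name] = lin

    # optional tandem arrays (for duplicate-type classification testing)
    for name in lineages:
        lin = lins[name]
        used_sources: set[str] = set()
        for _ in range(config.n_tandem_arrays):
            ci = int(rng.integers(len(lin.chroms)))
            cname, genes = lin.chroms[ci]
            if not genes:
                continue
            pos = int(rng.integers(len(genes)))
            src = genes[pos]
            if src.tandem_of is not None or _gene_id(name, src) in used_sources:
                continue
            used_sources.add(_gene_id(name, src))
            copies = [
                _Gene(src.anc, src.anc_chrom, src.path, src.orientation, (src.path, t + 1))
                for t in range(config.tandem_array_size - 1)
            ]
            lin.chroms[ci] = (cname, genes[: pos + 1] + copies + genes[pos + 1 :])

    # gene tables + bookkeeping
    tables: dict[str, GeneTable] = {}
    gene_index: dict[str, list[tuple[str, _Gene]]] = {}  # anc -> [(gene_id, gene)]
    lineage_of: dict[str, str] = {}
    for name in lineages:
        rows = []
        for cname, genes in lins[name].chroms:
            for i, g in enumerate(genes):
                gid = _gene_id(name, g)
                rows.append((cname, i * 1000, i * 1000 + 900, g.orientation, gid))
                gene_index.setdefault(g.anc, []).append((gid, g))
                lineage_of[gid] = name
                truth.ancestral_identity[gid] = (g.anc, g.anc_chrom)
                truth.subgenome[gid] = f"{name}:{''.join(g.path) or '-'}"
        tables[name] = GeneTable.from_records(name, rows)

    # true pairwise Ks for every homologous pair, plus homology hits
    dup_ages = {name: lins[name].dup_ages for name in lineages}
    hits: dict[tuple[str, str], list[HomologyHit]] = {}
    comparisons = [(a, a) for a in lineages] + list(itertools.combinations(lineages, 2))
    for comp in comparisons:
        hits[comp] = []
    for anc in sorted(gene_index):
        members = gene_index[anc]
        for (gid1, g1), (gid2, g2) in itertools.combinations(members, 2):
            l1, l2 = lineage_of[gid1], lineage_of[gid2]
            ks = _true_ks(l1, g1, l2, g2, dup_ages, config)
            truth.true_pair_ks[pair_id_for(gid1, gid2)] = ks
            comp = (l1, l2) if (l1, l2) in hits else (l2, l1)
            bitscore = _BITSCORE_S0 * math.exp(-_BITSCORE_LAMBDA * ks)
            identity = max(30.0, 100.0 * math.exp(-0.5 * ks))
            evalue = min(1e-6, 10.0 ** (-bitscore / 5.0))
            for q, s in ((gid1, gid2), (gid2, gid1)):
                hits[comp].append(
                    HomologyHit(
                        query_id=q,
                        subject_id=s,
                        identity_pct=identity,
                        bitscore=bitscore,
                        evalue=evalue,
                    )
                )

    observed_ks: dict[str, float] | None = None
    cds: dict[str, str] | None = None
    if config.sequence_mode == "table":
        observed_ks = {}
        for pid in sorted(truth.true_pair_ks):
            noise = rng.normal(0.0, config.ks_noise_sd) if config.ks_noise_sd else 0.0
            observed_ks[pid] = max(0.0, truth.true_pair_ks[pid] + noise)
    else:
        cds = {}
        codon_pool = np.array(FOURFOLD_CODONS)
        for anc in sorted(gene_index):
            members = gene_index[anc]
            root = [str(c) for c in rng.choice(codon_pool, size=config.codons_per_gene)]
            per_lineage: dict[str, list[tuple[str, _Gene]]] = {}
            for gid, g in members:
                per_lineage.setdefault(lineage_of[gid], []).append((gid, g))
            n_lin = len(per_lineage)
            for lname in lineages:
                if lname not in per_lineage:
                    continue
                t0 = config.divergence_ks if n_lin > 1 else (
                    dup_ages[lname][0] if dup_ages[lname] else 0.0
                )
                lineage_root = (
                    _evolve_seq(root, 0.0, config, rng) if n_lin > 1 else list(root)
                )
                events = [
                    (kind, age)
                    for kind, age in config.lineage_scripts[lname]
                    if kind in DUP_EVENTS
                ]
                needed = {g.path for _, g in per_lineage[lname]}
                leaves = _leaf_sequences(
                    lineage_root, t0, events, needed, config, rng
                )
                for gid, g in per_lineage[lname]:
                    seq = leaves.get(g.path)
                    if seq is None:  # zero-event lineage: leaf is the root path
                        seq = leaves.get(())
                    base = "".join(seq)
                    if g.tandem_of is not None:
                        base = "".join(
                            _evolve_seq(list(seq), config.tandem_ks / 2.0, config, rng)
                        )
                    cds[gid] = base

    return SimResult(
        tables=tables, hits=hits, observed_ks=observed_ks, cds=cds, truth=truth
    )


def emit_truth_tables(truth: SimTruth, outdir) -> list[Path]:
    """Write the ground-truth TSVs (events, pair Ks, loss runs, ancestry)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "true_events.tsv"
    write_tsv(
        p,
        ["lineage", "kind", "age_ks", "detail"],
        ([e.lineage, e.kind, f"{e.age:g}", e.detail] for e in truth.true_events),
    )
    paths.append(p)
    p = outdir / "true_pair_ks.tsv"
    write_tsv(
        p,
        ["pair_id", "ks"],
        ([pid, f"{ks:.6f}"] for pid, ks in sorted(truth.true_pair_ks.items())),
    )
    paths.append(p)
    p = outdir / "loss_runs.tsv"
    write_tsv(
        p,
        ["event", "run_length"],
        ([ev, r] for ev, runs in sorted(truth.loss_runs.items()) for r in runs),
    )
    paths.append(p)
    p = outdir / "ancestry.tsv"
    write_tsv(
        p,
        ["gene_id", "ancestral_gene", "ancestral_chrom", "subgenome"],
        (
            [gid, anc, chrom, truth.subgenome[gid]]
            for gid, (anc, chrom) in sorted(truth.ancestral_identity.items())
        ),
    )
    paths.append(p)
    return paths
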