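import filecmp
from collections import Counter

import numpy as np
import pytest

from wgdkit.io import ValidationError
from wgdkit.ng86 import ng86
from wgdkit.dotplot import rank_hits
from wgdkit.simdata import (
    FOURFOLD_CODONS,
    SimConfig,
    emit_truth_tables,
    sample_loss_run_lengths,
    simulate,
)

from oracles import oracle_geometric_mle


def test_zero_event_identity():
    cfg = SimConfig(
        n_chromosomes=2,
        genes_per_chromosome=50,
        lineage_scripts={"A": [], "B": []},
        divergence_ks=0.0,
        ks_noise_sd=0.0,
        seed=1,
    )
    res = simulate(cfg)
    assert res.tables["A"].n_genes == res.tables["B"].n_genes == 100
    assert set(res.truth.true_pair_ks.values()) == {0.0}
    # same ancestral order in both lineages
    a_anc = [res.truth.ancestral_identity[g.gene_id][0] for g in res.tables["A"]]
    b_anc = [res.truth.ancestral_identity[g.gene_id][0] for g in res.tables["B"]]
    assert a_anc == b_anc


@pytest.mark.parametrize(
    "script, factor",
    [
        ([("WGD", 0.6), ("WGD", 0.3)], 4),
        ([("WGT", 0.9)], 3),
        ([("WGT", 0.9), ("WGD", 0.3)], 6),
    ],
)
def test_copy_number_conservation_without_loss(script, factor):
    cfg = SimConfig(
        n_chromosomes=2,
        genes_per_chromosome=40,
        lineage_scripts={"B": script},
        divergence_ks=1.0,
        loss_initiation_rate=0.0,
        seed=3,
    )
    res = simulate(cfg)
    counts = Counter(
        anc for anc, _ in res.truth.ancestral_identity.values()
    )
    per_gene = Counter(
        res.truth.ancestral_identity[g.gene_id][0] for g in res.tables["B"]
    )
    assert set(per_gene.values()) == {factor}


def test_rearrangements_conserve_gene_count():
    cfg = SimConfig(
        n_chromosomes=4,
        genes_per_chromosome=50,
        lineage_scripts={
            "B": [("WGD", 0.5), ("EEJ", 0.4), ("NCF", 0.3), ("XO", 0.2), ("IV", 0.1)]
        },
        divergence_ks=1.0,
        loss_initiation_rate=0.0,
        seed=5,
    )
    res = simulate(cfg)
    assert res.tables["B"].n_genes == 2 * 4 * 50
    assert len(res.tables["B"].chromosomes) == 8 - 2  # two fusions


def test_generated_loss_runs_recover_extension_parameter():
    cfg = SimConfig(
        n_chromosomes=4,
        genes_per_chromosome=600,
        lineage_scripts={"B": [("WGD", 0.6), ("WGD", 0.3)]},
        divergence_ks=1.0,
        loss_extension_p=0.28,
        loss_initiation_rate=0.2,
        seed=11,
    )
    res = simulate(cfg)
    runs = [r for event in res.truth.loss_runs.values() for r in event]
    assert len(runs) >= 1000
    # truncation at chromosome ends or protected last copies is rare, so
    # the MLE on the recorded runs sits on the planted continuation
    # probability
    assert oracle_geometric_mle(runs) == pytest.approx(0.28, abs=0.02)


def test_direct_run_sampler_matches_geometric_law(rng):
    runs = sample_loss_run_lengths(5000, 0.28, rng)
    assert runs.min() >= 1
    assert oracle_geometric_mle(runs.tolist()) == pytest.approx(0.28, abs=0.02)


def test_best_hit_is_most_recent_relative():
    cfg = SimConfig(
        n_chromosomes=1,
        genes_per_chromosome=80,
        lineage_scripts={"B": [("WGD", 0.6), ("WGD", 0.3)]},
        divergence_ks=1.0,
        loss_initiation_rate=0.0,
        seed=7,
    )
    res = simulate(cfg)
    ks = res.truth.true_pair_ks
    ranked = rank_hits(res.hits[("B", "B")])
    for h in ranked:
        if h.rank != "best":
            continue
        pid = "|".join(sorted((h.query_id, h.subject_id)))
        others = [
            ks["|".join(sorted((h.query_id, g.gene_id)))]
            for g in res.tables["B"]
            if g.gene_id != h.query_id
            and "|".join(sorted((h.query_id, g.gene_id))) in ks
        ]
        assert ks[pid] == min(others)


def test_table_mode_noise_is_truncated_at_zero():
    cfg = SimConfig(
        n_chromosomes=1,
        genes_per_chromosome=150,
        lineage_scripts={"A": [], "B": []},
        divergence_ks=0.05,
        ks_noise_sd=0.1,
        seed=9,
    )
    res = simulate(cfg)
    vals = np.array(list(res.observed_ks.values()))
    assert vals.min() >= 0.0
    assert (vals == 0.0).any()  # truncation visible at this noise level
    assert vals.mean() > 0.05  # truncation shifts the mean upward


def test_sequence_mode_ng86_recovers_divergence():
    cfg = SimConfig(
        n_chromosomes=1,
        genes_per_chromosome=200,
        lineage_scripts={"A": [], "B": []},
        divergence_ks=0.3,
        sequence_mode="sequence",
        codons_per_gene=120,
        seed=13,
    )
    res = simulate(cfg)
    estimates = []
    for pid in res.truth.true_pair_ks:
        a, b = pid.split("|")
        r = ng86(res.cds[a], res.cds[b])
        assert r.status == "ok"
        estimates.append(r.Ks)
    estimates = np.array(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - 0.3) < 3 * se + 0.005


def test_fourfold_alphabet_has_exactly_one_synonymous_site_per_codon():
    from wgdkit.ng86 import _SYN_SITES

    assert len(FOURFOLD_CODONS) == 24
    for codon in FOURFOLD_CODONS:
        assert _SYN_SITES[codon] == pytest.approx(1.0)


def test_identical_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(n_chromosomes=2, genes_per_chromosome=40, seed=17)
    for d in ("run1", "run2"):
        res = simulate(cfg)
        emit_truth_tables(res.truth, tmp_path / d)
    for name in ("true_events.tsv", "true_pair_ks.tsv", "loss_runs.tsv", "ancestry.tsv"):
        assert filecmp.cmp(tmp_path / "run1" / name, tmp_path / "run2" / name, shallow=False)


def test_tandem_arrays_are_adjacent_and_low_ks():
    cfg = SimConfig(
        n_chromosomes=1,
        genes_per_chromosome=60,
        lineage_scripts={"A": []},
        divergence_ks=0.5,
        n_tandem_arrays=3,
        tandem_array_size=3,
        seed=19,
    )
    res = simulate(cfg)
    table = res.tables["A"]
    tandem = [g for g in table if "_t" in g.gene_id]
    assert len(tandem) == 3 * 2
    order = table.order_map()
    for g in tandem:
        src_id = g.gene_id.rsplit("_t", 1)[0]
        pid = "|".join(sorted((g.gene_id, src_id)))
        assert res.truth.true_pair_ks[pid] == cfg.tandem_ks
        assert abs(order[src_id][1] - g.order_index) <= cfg.tandem_array_size


@pytest.mark.parametrize(
    "overrides, match",
    [
        ({"loss_extension_p": 1.0}, "loss_extension_p"),
        ({"divergence_ks": -1.0}, "divergence_ks"),
        ({"lineage_scripts": {"B": [("WGD", 0.3), ("WGD", 0.6)]}}, "non-increasing"),
        ({"lineage_scripts": {"A": [], "B": [("WGD", 5.0)]}}, "predates"),
        ({"lineage_scripts": {"B": [("FLY", 0.3)]}}, "unknown event"),
    ],
)
def test_config_validation(overrides, match):
    cfg = SimConfig(**overrides)
    with pytest.raises(ValidationError, match=match):
        cfg.validate()
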