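from collections import Counter

import numpy as np
import pytest

from wgdkit.fractionation import (
    GeometricLossFit,
    RetentionProfile,
    fit_geometric,
    loss_runs,
    retention_profile,
)
from wgdkit.io import GeneTable, ValidationError
from wgdkit.simdata import SimConfig, sample_loss_run_lengths, simulate
from wgdkit.synteny import BlockPair, CollinearBlock

from oracles import oracle_geometric_mle


def _profile(presence, footprint=None):
    presence = np.asarray(presence, dtype=bool)
    footprint = (
        np.ones_like(presence) if footprint is None else np.asarray(footprint, bool)
    )
    return RetentionProfile(
        reference_id="R",
        presence={"sub": {"c1": presence}},
        footprint={"sub": {"c1": footprint}},
    )


def test_retention_rate_direct_count():
    profile = _profile([1, 0, 0, 1, 0, 1])
    assert profile.retention_rate() == pytest.approx(0.5)
    assert profile.loss_rate() == pytest.approx(0.5)


def test_runs_direct_enumeration():
    counts, excluded = loss_runs(_profile([1, 0, 0, 1, 0, 1]))
    assert counts == {1: 1, 2: 1}
    assert excluded == 0


def test_all_retained_gives_no_runs():
    counts, excluded = loss_runs(_profile([1] * 10))
    assert counts == {} and excluded == 0


def test_edge_touching_runs_are_not_counted():
    # absent genes at the footprint boundary are unbounded and skipped
    counts, _ = loss_runs(_profile([0, 0, 1, 0, 1, 0, 0]))
    assert counts == {1: 1}


def test_long_gap_counts_as_segmental_loss():
    presence = [1] + [0] * 40 + [1]
    counts, excluded = loss_runs(_profile(presence), segmental_cutoff=30)
    assert counts == {}
    assert excluded == 1


def test_gene_conservation_across_runs_and_retention():
    rng = np.random.default_rng(0)
    presence = rng.random(500) > 0.4
    presence[0] = presence[-1] = True  # avoid edge runs for exact accounting
    profile = _profile(presence)
    counts, excluded = loss_runs(profile, segmental_cutoff=500)
    lost_in_runs = sum(k * n for k, n in counts.items())
    retained = int(presence.sum())
    assert lost_in_runs + retained == len(presence)
    assert excluded == 0


def test_noiseless_geometric_counts_fit_exactly():
    counts = {1: 1024, 2: 512, 3: 256, 4: 128, 5: 64}
    fit = fit_geometric(counts)
    assert fit.p_hat == pytest.approx(0.5, abs=1e-9)
    assert fit.p_value == pytest.approx(1.0)
    assert fit.f_stat == 0.0


def test_power_law_counts_are_rejected():
    counts = {k: int(round(5000 / k**2)) for k in range(1, 9)}
    fit = fit_geometric(counts)
    assert fit.p_value < 0.05


def test_recovery_of_planted_extension_parameter(rng):
    runs = sample_loss_run_lengths(5000, 0.28, rng)
    counts = dict(Counter(runs.tolist()))
    fit = fit_geometric(counts)
    oracle = oracle_geometric_mle(runs.tolist())
    assert fit.p_mle == pytest.approx(oracle, abs=1e-12)
    assert abs(fit.p_mle - 0.28) < 0.02
    assert abs(fit.p_hat - 0.28) < 0.03
    assert fit.p_value > 0.05  # truly geometric data should not be rejected


def test_regression_and_mle_agree_on_geometric_data(rng):
    runs = sample_loss_run_lengths(2000, 0.35, rng)
    fit = fit_geometric(dict(Counter(runs.tolist())))
    assert abs(fit.p_hat - fit.p_mle) < 0.02


def test_too_few_run_lengths_rejected():
    with pytest.raises(ValidationError, match="3 distinct"):
        fit_geometric({1: 100, 2: 50})


def _truth_blocks(res, ref="A", query="B"):
    """Blocks reconstructed from simulator bookkeeping: one block per
    (reference chromosome, query subgenome), pairs for every surviving copy."""
    order_a = res.tables[ref].order_map()
    by_anc = {}
    for gid, (anc, _) in res.truth.ancestral_identity.items():
        by_anc.setdefault(anc, []).append(gid)
    blocks, assignment = [], {}
    groups = {}
    for anc, gids in by_anc.items():
        ref_genes = [g for g in gids if g.startswith(f"{ref}_")]
        qry_genes = [g for g in gids if g.startswith(f"{query}_")]
        for rg in ref_genes:
            chrom, idx = order_a[rg]
            for qg in qry_genes:
                sub = res.truth.subgenome[qg]
                groups.setdefault((chrom, sub), []).append(
                    BlockPair(idx, 0, rg, qg, f"{rg}|{qg}")
                )
    for i, ((chrom, sub), pairs) in enumerate(sorted(groups.items())):
        pairs = sorted(pairs)
        block = CollinearBlock(
            block_id=f"t{i}", chrom_a=chrom, chrom_b=sub, orientation=1, pairs=pairs
        )
        blocks.append(block)
        assignment[block.block_id] = sub
    return blocks, assignment


def test_retention_matches_simulator_bookkeeping_exactly():
    cfg = SimConfig(
        n_chromosomes=2,
        genes_per_chromosome=300,
        lineage_scripts={"A": [], "B": [("WGD", 0.4)]},
        divergence_ks=1.0,
        loss_extension_p=0.28,
        loss_initiation_rate=0.25,
        seed=21,
    )
    res = simulate(cfg)
    blocks, assignment = _truth_blocks(res)
    profile = retention_profile(res.tables["A"], blocks, assignment)
    # oracle: direct arithmetic on the truth pair lists -- distinct retained
    # reference positions over the footprint span, per subgenome block
    present = covered = 0
    for b in blocks:
        idx = {p.a_index for p in b.pairs}
        present += len(idx)
        covered += max(idx) - min(idx) + 1
    assert profile.retention_rate() == pytest.approx(present / covered, abs=1e-12)
    assert profile.loss_rate() > 0.2  # loss really happened under these rates


def test_loss_free_wgd_retains_everything():
    cfg = SimConfig(
        n_chromosomes=2,
        genes_per_chromosome=100,
        lineage_scripts={"A": [], "B": [("WGD", 0.4)]},
        divergence_ks=1.0,
        loss_initiation_rate=0.0,
        seed=2,
    )
    res = simulate(cfg)
    blocks, assignment = _truth_blocks(res)
    profile = retention_profile(res.tables["A"], blocks, assignment)
    assert profile.retention_rate() == 1.0


def test_empty_block_set_is_an_error(small_table):
    with pytest.raises(ValidationError, match="empty block set"):
        retention_profile(small_table, [], {})
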