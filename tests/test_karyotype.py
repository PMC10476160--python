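import numpy as np
import pytest

from wgdkit.io import ValidationError
from wgdkit.karyotype import (
    AdjacencyCall,
    KaryoEvent,
    Karyotype,
    Segment,
    apply_event,
    expected_dotplot,
    infer_fusion_timing,
    normalize,
    parse_script,
    read_karyotype,
    run_script,
    write_karyotype,
)


def _k(n, prefix="c"):
    return Karyotype.from_labels([f"{prefix}{i + 1}" for i in range(n)])


def test_eej_merges_and_records_satellite():
    k = apply_event(_k(3), KaryoEvent("EEJ", ("c1", "c2")))
    assert k.n_chromosomes == 2
    assert len(k.get("c1").segments) == 2
    assert len(k.satellites) == 1
    assert k.satellites[0].label == "S1"


def test_wgd_doubles_and_covers_every_span_twice():
    k = apply_event(_k(10), KaryoEvent("WGD"))
    assert k.n_chromosomes == 20
    lengths = k.ancestral_length()
    assert len(lengths) == 10
    assert all(v == pytest.approx(2.0) for v in lengths.values())


def test_wgt_triples():
    k = apply_event(_k(7, "E"), KaryoEvent("WGT"))
    assert k.n_chromosomes == 21
    assert all(v == pytest.approx(3.0) for v in k.ancestral_length().values())


def test_xo_preserves_count_and_content():
    k0 = _k(4)
    k = apply_event(
        k0, KaryoEvent("XO", ("c1", "c2"), params={"pos_a": 0.4, "pos_b": 0.7})
    )
    assert k.n_chromosomes == 4
    assert k.ancestral_length() == pytest.approx(k0.ancestral_length())
    # reciprocal exchange of the distal arms
    assert [s.ancestral_chrom for s in k.get("c1").segments] == ["c1", "c2"]
    assert k.get("c1").segments[0].hi == pytest.approx(0.4)
    assert k.get("c2").segments[0].hi == pytest.approx(0.7)


def test_ncf_nests_donor_inside_host():
    k = apply_event(
        _k(3), KaryoEvent("NCF", ("c1", "c2"), params={"pos": 0.5})
    )
    assert k.n_chromosomes == 2
    assert [s.ancestral_chrom for s in k.get("c1").segments] == ["c1", "c2", "c1"]
    assert len(k.satellites) == 1


def test_inversion_twice_is_identity():
    k0 = _k(2)
    iv = KaryoEvent("IV", ("c1",), params={"lo": 0.25, "hi": 0.8})
    k2 = apply_event(apply_event(k0, iv), iv)
    assert normalize(k2.get("c1").segments) == k0.get("c1").segments


def test_inversion_flips_orientation():
    k = apply_event(_k(1), KaryoEvent("IV", ("c1",), params={"lo": 0.2, "hi": 0.6}))
    segs = k.get("c1").segments
    assert [s.orientation for s in segs] == [1, -1, 1]
    assert segs[1].lo == pytest.approx(0.2) and segs[1].hi == pytest.approx(0.6)


def test_degenerate_breakpoints_rejected():
    with pytest.raises(ValidationError, match="strictly inside"):
        apply_event(_k(2), KaryoEvent("XO", ("c1", "c2"), params={"pos_a": 0.0, "pos_b": 0.5}))
    with pytest.raises(ValidationError, match="no chromosome"):
        apply_event(_k(2), KaryoEvent("EEJ", ("c1", "nope")))


def _random_script(rng, karyotype, n_events=12):
    events = []
    k = karyotype
    for _ in range(n_events):
        names = [c.name for c in k.chromosomes]
        kinds = ["XO", "IV", "EEJ", "NCF"] if len(names) > 2 else ["IV"]
        kind = kinds[int(rng.integers(len(kinds)))]
        pos = lambda: float(rng.uniform(0.1, 0.9))
        if kind == "IV":
            lo = float(rng.uniform(0.05, 0.5))
            ev = KaryoEvent("IV", (names[int(rng.integers(len(names)))],),
                            params={"lo": lo, "hi": lo + float(rng.uniform(0.1, 0.4))})
        else:
            i, j = rng.choice(len(names), size=2, replace=False)
            a, b = names[int(i)], names[int(j)]
            if kind == "XO":
                ev = KaryoEvent("XO", (a, b), params={"pos_a": pos(), "pos_b": pos()})
            elif kind == "EEJ":
                ev = KaryoEvent("EEJ", (a, b))
            else:
                ev = KaryoEvent("NCF", (a, b), params={"pos": pos()})
        events.append(ev)
        k = apply_event(k, ev)
    return events, k


def test_count_algebra_and_content_conservation_on_random_scripts(rng):
    deltas = {"EEJ": -1, "NCF": -1, "XO": 0, "IV": 0}
    for trial in range(8):
        k = _k(int(rng.integers(6, 12)))
        baseline = k.ancestral_length()
        events, final = _random_script(rng, k)
        count = k.n_chromosomes
        fusions = 0
        for ev in events:
            count += deltas[ev.kind]
            fusions += ev.kind in ("EEJ", "NCF")
        assert final.n_chromosomes == count
        assert final.ancestral_length() == pytest.approx(baseline)
        # satellite ledger: one satellite per fusion event
        assert len(final.satellites) == fusions


def test_run_script_logs_counts_and_reports_failing_step():
    k = _k(4)
    events = parse_script("EEJ c1 c2\nXO c1@0.5 c3@0.5\nEEJ c1 c2")
    with pytest.raises(ValidationError, match="step 3"):
        run_script(k, events)
    final, log = run_script(k, events[:2])
    assert [entry[2] for entry in log] == [3, 3]


class TestScriptParsing:
    def test_dsl_round_trip(self):
        script = "EEJ c1 c2\nNCF host=c3 donor=c4 pos=0.25\nXO c1@0.4 c5@0.7\nIV c6@0.2-0.6\nWGD\nWGT"
        events = parse_script(script)
        assert [e.kind for e in events] == ["EEJ", "NCF", "XO", "IV", "WGD", "WGT"]
        assert events[1].params["pos"] == 0.25
        assert events[2].params == {"pos_a": 0.4, "pos_b": 0.7}

    def test_bad_lines_report_line_number(self):
        with pytest.raises(ValidationError, match="line 2"):
            parse_script("WGD\nFLIP c1")


class TestExpectedDotplot:
    def test_self_comparison_is_one_diagonal_per_chromosome(self):
        k = _k(3)
        tracts = expected_dotplot(k, k)
        assert len(tracts) == 3
        for name, iv1, name2, iv2, orient in tracts:
            assert name == name2 and iv1 == iv2 == (0.0, 1.0) and orient == 1

    def test_wgd_doubles_every_tract(self):
        k = _k(3)
        post = apply_event(k, KaryoEvent("WGD"))
        tracts = expected_dotplot(k, post)
        assert len(tracts) == 6
        for c in k.chromosomes:
            assert sum(t[0] == c.name for t in tracts) == 2

    def test_fusion_junction_shows_two_tracts_on_one_chromosome(self):
        k = _k(2)
        fused = apply_event(k, KaryoEvent("EEJ", ("c1", "c2")))
        tracts = expected_dotplot(fused, k)
        assert {t[0] for t in tracts} == {"c1"}
        assert len(tracts) == 2
        ivs = sorted(t[1] for t in tracts)
        assert ivs[0][1] == pytest.approx(ivs[1][0])  # tracts meet at the junction

    def test_disjoint_label_sets_give_empty_list(self):
        assert expected_dotplot(_k(2, "x"), _k(2, "y")) == []


class TestFusionTiming:
    def test_fusion_before_wgd_is_seen_twice(self):
        anc = _k(3, "B")
        pre = apply_event(anc, KaryoEvent("EEJ", ("B1", "B2")))
        post = apply_event(pre, KaryoEvent("WGD"))
        calls = infer_fusion_timing(post, anc)
        assert [(c.chrom_a, c.chrom_b, c.copies, c.timing) for c in calls] == [
            ("B1", "B2", 2, "pre_wgd")
        ]

    def test_fusion_after_wgd_is_seen_once(self):
        anc = _k(3, "B")
        dup = apply_event(anc, KaryoEvent("WGD"))
        post = apply_event(dup, KaryoEvent("EEJ", ("B1a", "B2a")))
        calls = infer_fusion_timing(post, anc)
        assert [(c.copies, c.timing) for c in calls] == [(1, "post_wgd")]

    def test_shared_telomere_junction_of_two_descendants(self):
        # analogue of two ancestral chromosomes whose joined telomeres appear
        # in two descendant chromosomes: the fusion must predate the WGD
        anc = _k(7, "B")
        pre = apply_event(anc, KaryoEvent("EEJ", ("B2", "B4")))
        post = apply_event(pre, KaryoEvent("WGD"))
        # further independent rearrangement that keeps both junction copies
        post = apply_event(
            post, KaryoEvent("XO", ("B3a", "B5b"), params={"pos_a": 0.5, "pos_b": 0.5})
        )
        calls = {(c.chrom_a, c.chrom_b): c.timing for c in infer_fusion_timing(post, anc)}
        assert calls[("B2", "B4")] == "pre_wgd"

    def test_disrupted_junction_is_flagged_not_misclassified(self):
        anc = _k(3, "B")
        pre = apply_event(anc, KaryoEvent("EEJ", ("B1", "B2")))
        post = apply_event(pre, KaryoEvent("WGD"))
        # a crossover through one junction copy leaves a singleton junction
        broken = apply_event(
            post, KaryoEvent("XO", ("B1b", "B3a"), params={"pos_a": 0.5, "pos_b": 0.5})
        )
        calls = {(c.chrom_a, c.chrom_b): c.timing for c in infer_fusion_timing(broken, anc)}
        assert calls[("B1", "B2")] == "ambiguous"

    def test_rule_refused_without_wgd(self):
        anc = _k(2, "B")
        fused = apply_event(anc, KaryoEvent("EEJ", ("B1", "B2")))
        with pytest.raises(ValidationError, match="whole-genome duplication"):
            infer_fusion_timing(fused, anc)


def test_karyotype_tsv_round_trip(tmp_path):
    k = apply_event(_k(3), KaryoEvent("XO", ("c1", "c2"), params={"pos_a": 0.3, "pos_b": 0.6}))
    path = tmp_path / "karyotype.tsv"
    write_karyotype(k, path)
    back = read_karyotype(path)
    assert {c.name: c.segments for c in back.chromosomes} == {
        c.name: c.segments for c in k.chromosomes
    }
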