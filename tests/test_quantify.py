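"""Read classification, positional/combination tables, indels, deamination."""

import numpy as np
import pytest

from ampedit.locus import AmpliconLocus
from ampedit.quantify import (EmptyTableError, classify_sequence, flag_above_background,
                              quantify_cytosine_deamination, quantify_reads,
                              summarize_timecourse, tabulate_combinations)
from ampedit.reads import process_read_pairs
from ampedit.simulate import IndelSpec, SimConfig, simulate_amplicon_reads


def mutate(seq, idx, base):
    s = list(seq)
    s[idx] = base
    return "".join(s)


@pytest.fixture(scope="module")
def interior(locus):
    return locus.interior


class TestClassification:
    def test_reference_identical_read_is_wt(self, locus, interior):
        cr = classify_sequence(interior, locus)
        assert cr.read_class.kind == "WT"
        assert cr.proto_bases == locus.protospacer

    def test_single_a9_edit(self, locus, interior):
        idx = locus.interior_index(9)
        cr = classify_sequence(mutate(interior, idx, "G"), locus)
        assert cr.read_class.kind == "EDIT"
        assert cr.read_class.edited == {"A9"}
        assert cr.read_class.label == "A9"

    def test_a9_plus_a12(self, locus, interior):
        seq = mutate(interior, locus.interior_index(9), "G")
        seq = mutate(seq, locus.interior_index(12), "G")
        cr = classify_sequence(seq, locus)
        assert cr.read_class.edited == {"A9", "A12"}
        assert cr.read_class.label == "A9+A12"

    def test_edit_takes_precedence_over_other_substitution(self, locus, interior):
        seq = mutate(interior, locus.interior_index(9), "G")
        seq = mutate(seq, locus.interior_index(5), "T")   # C5>T deamination
        cr = classify_sequence(seq, locus)
        assert cr.read_class.kind == "EDIT"
        assert cr.read_class.edited == {"A9"}

    def test_cytosine_substitution_alone_is_subst_other(self, locus, interior):
        seq = mutate(interior, locus.interior_index(5), "T")
        assert classify_sequence(seq, locus).read_class.kind == "SUBST_OTHER"

    def test_substitution_outside_protospacer_is_wt(self, locus, interior):
        lo, hi = locus.proto_interior_span
        idx = hi + 15  # beyond the protospacer
        base = "A" if interior[idx] != "A" else "C"
        assert classify_sequence(mutate(interior, idx, base),
                                 locus).read_class.kind == "WT"

    def test_eight_bp_duplication_is_indel(self, locus, interior):
        lo, hi = locus.proto_interior_span
        a, b = lo + 4, lo + 12          # protospacer positions 5..12
        seq = interior[:b] + interior[a:b] + interior[b:]
        cr = classify_sequence(seq, locus)
        assert cr.read_class.kind == "INDEL"
        assert len(cr.indels) == 1
        ev = cr.indels[0]
        assert ev.type == "duplication"
        assert ev.size == 8
        assert 1 <= ev.span[0] <= 20

    def test_deletion_inside_protospacer_is_indel(self, locus, interior):
        lo, hi = locus.proto_interior_span
        seq = interior[:lo + 6] + interior[lo + 9:]
        cr = classify_sequence(seq, locus)
        assert cr.read_class.kind == "INDEL"
        ev = cr.indels[0]
        assert ev.type == "deletion"
        assert ev.size == 3
        assert ev.span == (7, 9)

    def test_distant_indel_is_not_flagged(self, locus, interior):
        # a deletion far outside the protospacer window leaves the class
        # determined by the protospacer content
        lo, hi = locus.proto_interior_span
        assert hi + 12 < len(interior) - 3
        seq = interior[:hi + 12] + interior[hi + 14:]
        cr = classify_sequence(seq, locus)
        assert cr.read_class.kind == "WT"


class TestSampleQuantification:
    def test_all_wt_reads(self, locus, interior):
        q = quantify_reads([interior] * 1000, locus)
        assert q.position_table.base_frequency(9, "A") == 1.0
        combos = tabulate_combinations(q)
        assert combos.loc[combos["combination"] == "WT", "fraction"].item() == 1.0

    def test_mixture_fractions_exact(self, locus, interior):
        edited = mutate(interior, locus.interior_index(9), "G")
        q = quantify_reads([edited] * 600 + [interior] * 400, locus)
        assert q.position_table.base_frequency(9, "G") == pytest.approx(0.6)
        combos = tabulate_combinations(q).set_index("combination")
        assert combos.loc["A9", "fraction"] == pytest.approx(0.6)
        assert combos.loc["WT", "fraction"] == pytest.approx(0.4)

    def test_partition_property(self, locus):
        config = SimConfig(locus=locus, depth=3000, per_base_error=2e-3,
                           cytosine_rates={"C5": {"C>T": 0.002}},
                           indel_specs=(IndelSpec("duplication", (5, 12), 0.01),),
                           seed=13)
        pairs, _ = simulate_amplicon_reads(config)
        anchored, _ = process_read_pairs(pairs, locus)
        q = quantify_reads(anchored, locus)
        assert sum(q.class_counts.values()) == q.n_retained
        fr = tabulate_combinations(q)["fraction"].sum()
        assert fr == pytest.approx(1.0)

    def test_indel_frequency_over_all_retained_reads(self, locus, interior):
        lo, hi = locus.proto_interior_span
        dup = interior[:hi] + interior[hi - 8:hi] + interior[hi:]
        q = quantify_reads([dup] * 10 + [interior] * 90, locus)
        assert len(q.indel_records) == 1
        assert q.indel_records[0].frequency == pytest.approx(0.10)
        # positional coverage excludes the 10 indel reads
        assert q.position_table.coverage.max() == 90

    def test_empty_input_raises(self, locus):
        with pytest.raises(EmptyTableError):
            quantify_reads([], locus)


class TestStrandCorrectness:
    def test_minus_strand_locus_gives_identical_summaries(self, locus,
                                                          minus_locus):
        config = SimConfig(locus=locus, depth=1500, per_base_error=1e-3,
                           cytosine_rates={"C5": {"C>T": 0.01}},
                           seed=21)
        pairs, _ = simulate_amplicon_reads(config)
        anchored_plus, _ = process_read_pairs(pairs, locus)
        q_plus = quantify_reads(anchored_plus, locus)

        # same reads processed against the minus-strand description
        anchored_minus, _ = process_read_pairs(pairs, minus_locus)
        q_minus = quantify_reads(anchored_minus, minus_locus)

        np.testing.assert_array_equal(q_plus.position_table.counts,
                                      q_minus.position_table.counts)
        assert q_plus.class_counts == q_minus.class_counts


class TestDerivedSummaries:
    def test_cytosine_deamination_recovery(self, locus):
        config = SimConfig(locus=locus, depth=20000, per_base_error=0.0,
                           low_q_rate=0.0,
                           cytosine_rates={"C5": {"C>T": 0.02, "C>G": 0.01}},
                           seed=31)
        pairs, truth = simulate_amplicon_reads(config)
        anchored, _ = process_read_pairs(pairs, locus)
        q = quantify_reads(anchored, locus)
        cyto = quantify_cytosine_deamination(q.position_table, locus)
        row = cyto.set_index("position").loc["C5"]
        assert row["C>T"] == pytest.approx(
            truth.cytosine_counts[("C5", "C>T")] / 20000, abs=1e-9)
        c3 = cyto.set_index("position").loc["C3"]
        assert c3.sum() == 0.0

    def test_named_position_must_match_reference_base(self, locus):
        # the base-identity contract is enforced at locus construction
        with pytest.raises(ValueError):
            AmpliconLocus(
                name=locus.name, reference=locus.reference,
                protospacer_start=locus.protospacer_start,
                fwd_primer=locus.fwd_primer, rev_primer=locus.rev_primer,
                named_positions={"C1": 1})   # position 1 is a T

    def test_background_flagging(self, locus, interior):
        edited = mutate(interior, locus.interior_index(9), "G")
        post = quantify_reads([edited] * 250 + [interior] * 750,
                              locus).position_table
        controls = [quantify_reads([interior] * 1000, locus,
                                   f"ctrl{i}").position_table
                    for i in range(3)]
        flags = flag_above_background(post, controls, locus)
        flagged = flags[flags["flagged"]]
        assert {(9, "G")} == set(zip(flagged["position"], flagged["alt"]))

    def test_flagging_identical_to_controls_is_silent(self, locus, interior):
        t = quantify_reads([interior] * 500, locus).position_table
        flags = flag_above_background(t, [t, t], locus)
        assert not flags["flagged"].any()

    def test_timecourse_order_and_duplicates(self, locus, interior):
        t = quantify_reads([interior] * 10, locus).position_table
        df = summarize_timecourse([("d7", t), ("d30", t)], locus)
        assert list(df["timepoint"].unique()) == ["d7", "d30"]
        assert set(df["position"]) == set(locus.named_positions)
        with pytest.raises(ValueError):
            summarize_timecourse([("d7", t), ("d7", t)], locus)
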