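import numpy as np
import pytest

from ampliconid import references
from ampliconid.amplicondb import ReferenceAmplicon, ReferenceDB, concretize, reverse_complement
from ampliconid.readpipe import (
    CollapsedSequence,
    Read,
    SampleSheet,
    assign,
    collapse,
    demultiplex,
    filter_min_count,
    mixture_report,
    quality_filter,
    run_pipeline,
    trim_and_orient,
)
from ampliconid.simulator import SimConfig, simulate

WOLF = references.MAMMAL_TARGETS["Canis lupus"]
SEAL = references.MAMMAL_TARGETS["Phoca vitulina"]


def make_read(rid, seq, q=30):
    return Read(rid, seq, chr(q + 33) * len(seq))


class TestQualityFilter:
    def test_all_high_quality_kept(self):
        reads = [make_read(f"r{i}", "ACGT", q=40) for i in range(5)]
        assert quality_filter(reads, 20) == reads

    def test_low_quality_dropped(self):
        good = [make_read("g1", "ACGT", q=30), make_read("g2", "ACGT", q=30)]
        bad = make_read("b", "ACGT", q=10)
        kept = quality_filter([good[0], bad, good[1]], 20)
        assert kept == good

    def test_empty(self):
        assert quality_filter([], 20) == []

    def test_threshold_is_inclusive(self):
        assert quality_filter([make_read("r", "ACGT", q=20)], 20)


class TestSampleSheet:
    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            SampleSheet({"s1": "ACGTACGTAC", "s2": "ACGTACGTAC"})

    def test_mixed_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            SampleSheet({"s1": "ACGTACGTAC", "s2": "ACGT"})

    def test_from_tsv(self, tmp_path):
        p = tmp_path / "sheet.tsv"
        p.write_text("sample\tfwd_barcode\ns1\tACGTACGTAC\ns2\tTGCATGCATG\n")
        sheet = SampleSheet.from_tsv(p)
        assert sheet.barcodes == {"s1": "ACGTACGTAC", "s2": "TGCATGCATG"}


class TestDemultiplex:
    sheet = SampleSheet({"A": "ACGTACGTAC", "B": "TGCATGCATG"})

    def test_forward_match(self):
        r = make_read("r1", "ACGTACGTAC" + WOLF)
        routed, unmatched = demultiplex([r], self.sheet)
        assert routed["A"] == [r] and not unmatched

    def test_reverse_complement_reoriented(self):
        r = make_read("r1", reverse_complement("ACGTACGTAC" + WOLF))
        routed, unmatched = demultiplex([r], self.sheet)
        assert len(routed["A"]) == 1 and not unmatched
        assert routed["A"][0].sequence.startswith("ACGTACGTAC")

    def test_no_match_goes_unmatched(self):
        r = make_read("r1", "GGGGGGGGGG" + WOLF)
        routed, unmatched = demultiplex([r], self.sheet)
        assert unmatched == [r] and not routed["A"] and not routed["B"]


class TestTrimAndOrient:
    def decorated(self, target, fwd, rev, barcode="ACGTACGTAC", tail="AA"):
        return barcode + fwd.sequence + target + reverse_complement(concretize(rev.sequence)) + tail

    def test_recovers_target(self, fwd, rev):
        seq = self.decorated(WOLF, fwd, rev)
        assert trim_and_orient(seq, fwd, rev) == WOLF

    def test_truncated_read_returns_none(self, fwd, rev):
        seq = "ACGTACGTAC" + fwd.sequence + WOLF[:30]
        assert trim_and_orient(seq, fwd, rev) is None

    def test_substitution_in_forward_primer_tolerated(self, fwd, rev):
        mutated_fwd = fwd.sequence[:5] + "T" + fwd.sequence[6:]
        assert mutated_fwd != fwd.sequence
        seq = "ACGTACGTAC" + mutated_fwd + WOLF + reverse_complement(concretize(rev.sequence))
        assert trim_and_orient(seq, fwd, rev, max_mismatches=2) == WOLF

    def test_degenerate_reverse_site_both_realizations(self, fwd, rev):
        for base in "AG":
            concrete = rev.sequence.replace("R", base)
            seq = fwd.sequence + WOLF + reverse_complement(concrete)
            assert trim_and_orient(seq, fwd, rev) == WOLF

    def test_read_object_accepted(self, fwd, rev):
        r = make_read("r1", self.decorated(SEAL, fwd, rev))
        assert trim_and_orient(r, fwd, rev) == SEAL


class TestCollapseAndFilter:
    def test_collapse_counts_and_order(self):
        out = collapse(["X"] * 5 + ["Y"] * 2)
        assert out == [CollapsedSequence("X", 5), CollapsedSequence("Y", 2)]

    def test_collapse_tie_broken_lexicographically(self):
        out = collapse(["B", "A", "B", "A"])
        assert out == [CollapsedSequence("A", 2), CollapsedSequence("B", 2)]

    def test_collapse_empty_and_singletons(self):
        assert collapse([]) == []
        assert all(c.count == 1 for c in collapse(["A", "C", "G"]))

    def test_collapse_conserves_reads(self):
        rng = np.random.default_rng(1)
        targets = [f"SEQ{int(i)}" for i in rng.integers(0, 10, size=500)]
        assert sum(c.count for c in collapse(targets)) == 500

    def test_min_count_threshold_keeps_boundary(self):
        collapsed = [
            CollapsedSequence("A", 25),
            CollapsedSequence("B", 20),
            CollapsedSequence("C", 19),
        ]
        kept = filter_min_count(collapsed, 20)
        assert [c.count for c in kept] == [25, 20]

    def test_min_count_identity_and_empty(self):
        collapsed = [CollapsedSequence("A", 3), CollapsedSequence("B", 1)]
        assert filter_min_count(collapsed, 1) == collapsed
        assert filter_min_count(collapsed, 50) == []


class TestAssign:
    def test_exact_hit(self, mammal_db):
        [a] = assign([CollapsedSequence(WOLF, 100)], mammal_db)
        assert a.status == "exact"
        assert a.resolved_label == "Canis lupus"
        assert a.taxa == (("Canis lupus", 0),)

    def test_shared_target_is_ambiguous_with_group_label(self):
        db = ReferenceDB(
            entries=[
                ReferenceAmplicon("Canis lupus", WOLF),
                ReferenceAmplicon("Canis familiaris", WOLF),
            ]
        )
        [a] = assign([CollapsedSequence(WOLF, 50)], db)
        assert a.status == "ambiguous"
        assert a.resolved_label == "Canis (2 spp.)"
        assert {t[0] for t in a.taxa} == {"Canis familiaris", "Canis lupus"}
        assert all(d == 0 for _, d in a.taxa)

    def test_near_hit_within_distance(self, mammal_db):
        query = "G" + WOLF[1:-1] + "C"  # 2 substitutions
        [a] = assign([CollapsedSequence(query, 30)], mammal_db, max_distance=3)
        assert a.status == "near"
        assert a.resolved_label == "Canis lupus"
        assert a.taxa[0][1] == 2

    def test_distant_query_unassigned(self, mammal_db):
        query = "ACGT" * 19
        [a] = assign([CollapsedSequence(query, 30)], mammal_db, max_distance=3)
        assert a.status == "unassigned" and a.resolved_label is None

    def test_every_reference_self_assigns(self, mammal_db):
        collapsed = [CollapsedSequence(e.target, 20) for e in mammal_db]
        for entry, a in zip(mammal_db, assign(collapsed, mammal_db)):
            assert a.status == "exact"
            assert a.resolved_label == entry.species

    def test_margin_prevents_confusion_between_close_species(self):
        # two references 1 nt apart; a read 1 error off each is ambiguous
        t1 = SEAL
        t2 = "A" + SEAL[1:]
        db = ReferenceDB(
            entries=[ReferenceAmplicon("X a", t1), ReferenceAmplicon("Y b", t2)]
        )
        query = "C" + SEAL[1:]  # distance 1 to both
        [a] = assign([CollapsedSequence(query, 30)], db, max_distance=3, min_margin=1)
        assert a.status == "ambiguous"


class TestMixtureReport:
    def test_fraction_arithmetic(self, mammal_db):
        assignments = assign(
            [CollapsedSequence(WOLF, 16190), CollapsedSequence(SEAL, 164)], mammal_db
        )
        rep = mixture_report(assignments)
        assert rep.fractions["Canis lupus"] == pytest.approx(16190 / 16354)
        assert rep.fractions["Phoca vitulina"] == pytest.approx(164 / 16354)
        assert rep.detected == {"Canis lupus": True, "Phoca vitulina": True}

    def test_single_taxon(self, mammal_db):
        rep = mixture_report(assign([CollapsedSequence(WOLF, 99)], mammal_db))
        assert rep.fractions == {"Canis lupus": 1.0}

    def test_empty(self):
        rep = mixture_report([])
        assert rep.taxon_counts == {} and rep.total_assigned == 0

    def test_fractions_sum_to_one(self, mammal_db):
        targets = [WOLF, SEAL, references.MAMMAL_TARGETS["Sus scrofa"]]
        assignments = assign(
            [CollapsedSequence(t, 20 + i) for i, t in enumerate(targets)], mammal_db
        )
        rep = mixture_report(assignments)
        assert sum(rep.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestPipeline:
    def test_zero_error_two_species_mix(self, mammal_db, fwd, rev):
        config = SimConfig(
            weights={"Canis lupus": 1, "Phoca vitulina": 1},
            n_reads=2000,
            substitution_rate=0.0,
            homopolymer_indel_rate=0.0,
            fwd_primer=fwd.sequence,
            rev_primer=rev.sequence,
            seed=11,
        )
        reads, truth = simulate(config, mammal_db)
        result = run_pipeline(reads, mammal_db, fwd, rev, min_count=20)
        res = result.samples["sample"]
        assert len(res.collapsed) == 2
        assert all(a.status == "exact" for a in res.assignments)
        frac = res.report.fractions["Canis lupus"]
        sd = (0.5 * 0.5 / 2000) ** 0.5
        assert abs(frac - 0.5) <= 3 * sd

    def test_read_count_conservation_with_demux(self, mammal_db, fwd, rev):
        sheet = SampleSheet({"s1": "ACGTACGTAC", "s2": "TGCATGCATG"})
        reads = []
        for i, (sample, bc) in enumerate(sheet.barcodes.items()):
            config = SimConfig(
                weights={"Canis lupus": 3, "Sus scrofa": 1},
                n_reads=400,
                substitution_rate=0.01,
                barcode=bc,
                fwd_primer=fwd.sequence,
                rev_primer=rev.sequence,
                seed=100 + i,
            )
            batch, _ = simulate(config, mammal_db)
            reads += [Read(f"{sample}_{r.id}", r.sequence, r.qual) for r in batch]
        # orphans: unmatched barcode and a low-quality read
        reads.append(make_read("orphan", "GGGGGGGGGG" + WOLF))
        reads.append(make_read("lowq", "ACGTACGTAC" + WOLF, q=5))

        result = run_pipeline(reads, mammal_db, fwd, rev, sheet=sheet, min_count=20)
        run_acc = result.accounting
        per_sample = [r.accounting for r in result.samples.values()]
        assert run_acc["input"] == len(reads)
        assert run_acc["low_quality"] == 1
        assert run_acc["unmatched"] == 1
        total_routed = sum(a["input"] for a in per_sample)
        assert (
            run_acc["low_quality"] + run_acc["unmatched"] + total_routed
            == run_acc["input"]
        )
        for acc in per_sample:
            assert acc["trim_failed"] + acc["trimmed"] == acc["input"]
            assert acc["kept_reads"] + acc["below_min_count_reads"] == acc["trimmed"]
            assert acc["assigned_reads"] + acc["unassigned_reads"] == acc["kept_reads"]

    def test_minor_component_needs_depth(self, mammal_db, fwd, rev):
        """At 1,500 reads a 1% minor component usually falls below the
        20-read filter; at 20,000 reads it is comfortably detected."""
        detected = {1500: 0, 20000: 0}
        for n in detected:
            config = SimConfig(
                weights={"Ursus arctos": 99, "Canis lupus": 1},
                n_reads=n,
                substitution_rate=0.0014,
                fwd_primer=fwd.sequence,
                rev_primer=rev.sequence,
                seed=5,
            )
            reads, _ = simulate(config, mammal_db)
            rep = run_pipeline(reads, mammal_db, fwd, rev, min_count=20).samples[
                "sample"
            ].report
            detected[n] = "Canis lupus" in rep.detected
        assert detected[20000] and not detected[1500]


class TestCollapseProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.sampled_from(["AC", "ACG", "ACGT", "TTTT"]), max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_collapse_partitions_input(self, targets):
        out = collapse(targets)
        assert sum(c.count for c in out) == len(targets)
        assert len({c.sequence for c in out}) == len(out)
        assert {c.sequence for c in out} == set(targets)
        counts = [c.count for c in out]
        assert counts == sorted(counts, reverse=True)
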