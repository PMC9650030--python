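"""Adapter detection, clipping, placement and junction bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import adapter_scan_naive, binom_tail_enum
from rtcseq import ligation, synth
from rtcseq.types import (
    AdapterSpec,
    DomainAnnotation,
    LigationEvent,
    TranscriptRecord,
    reverse_complement,
    rna_to_dna,
)

ADAPTER = AdapterSpec()
CORE = ADAPTER.core

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestFindAdapter:
    def test_constructed_read(self):
        read = "ACGTACGTAC" + "TTAC" + CORE
        m = ligation.find_adapter(read, ADAPTER)
        assert m.core_start == 14
        assert m.target_len == 10
        assert m.mismatches == 0

    def test_absent_core_is_none(self):
        assert ligation.find_adapter("ACGT" * 10, ADAPTER) is None

    def test_single_substitution_needs_tolerance(self):
        mutated = "C" + CORE[1:]  # core starts with T
        read = "ACGTACGTAC" + "TTAC" + mutated
        assert ligation.find_adapter(read, AdapterSpec(max_mismatches=0)) is None
        m = ligation.find_adapter(read, AdapterSpec(max_mismatches=1))
        assert m is not None and m.core_start == 14 and m.mismatches == 1

    def test_truncated_core_at_read_end(self):
        read = "A" * 20 + "GGCC" + CORE[:12]
        m = ligation.find_adapter(read, ADAPTER, min_core_prefix=12)
        assert m is not None and m.core_start == 24
        assert ligation.find_adapter(read, ADAPTER, min_core_prefix=13) is None

    def test_empty_read_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            ligation.find_adapter("", ADAPTER)

    @given(prefix=dna, suffix=dna, mm=st.integers(0, 2))
    @settings(max_examples=80, deadline=None)
    def test_agrees_with_naive_scan(self, prefix, suffix, mm):
        read = prefix + CORE + suffix
        adapter = AdapterSpec(max_mismatches=mm)
        got = ligation.find_adapter(read, adapter, min_core_prefix=12)
        want = adapter_scan_naive(read, CORE, mm, 12)
        assert want is not None
        assert (got.core_start, got.mismatches) == want


class TestClipRead:
    def test_clip_returns_target(self):
        read = "A" * 35 + "TTAC" + CORE
        m = ligation.find_adapter(read, ADAPTER)
        target, reason = ligation.clip_read(read, m, ADAPTER)
        assert reason is None and len(target) == 35

    def test_empty_target_discarded(self):
        read = "TTAC" + CORE  # adapter only
        m = ligation.find_adapter(read, ADAPTER)
        target, reason = ligation.clip_read(read, m, ADAPTER)
        assert target is None and reason == "empty_target"

    def test_short_target_discarded(self):
        read = "A" * 10 + "TTAC" + CORE
        m = ligation.find_adapter(read, ADAPTER)
        target, reason = ligation.clip_read(read, m, ADAPTER, min_target_len=15)
        assert target is None and reason == "short_target"

    @given(target_len=st.integers(15, 40))
    @settings(max_examples=20, deadline=None)
    def test_length_conservation(self, target_len):
        """clipped length + adapter bases account for the whole read."""
        rng = np.random.default_rng(target_len)
        target = "".join(rng.choice(list("AC"), size=target_len))
        read = target + "GGTT" + CORE
        m = ligation.find_adapter(read, ADAPTER)
        clipped, reason = ligation.clip_read(read, m, ADAPTER)
        assert reason is None
        assert len(clipped) + ADAPTER.n_random_5p + len(CORE) == len(read)


class TestMapClipped:
    @pytest.fixture()
    def refs(self):
        return [
            TranscriptRecord("t1", "ACGTACGGTTCAGGCATTACGATGACCGATGG", "CDS"),
            TranscriptRecord("t2", "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA", "CDS"),
        ]

    def test_unique_placement(self, refs):
        p = ligation.map_clipped("GGTTCAGGCATTACG", refs)
        assert (p.transcript_id, p.start, p.strand) == ("t1", 7, "+")

    def test_shared_sequence_is_ambiguous(self, refs):
        shared = refs[1].sequence[:16]
        both = refs + [TranscriptRecord("t3", "AA" + shared + "CC", "CDS")]
        p, reason = ligation.map_clipped(shared, both, with_reason=True)
        assert p is None and reason == "ambiguous"

    def test_one_substitution_recovered(self, refs):
        query = list("GGTTCAGGCATTACG")
        query[7] = "C" if query[7] != "C" else "A"
        p = ligation.map_clipped("".join(query), refs, max_map_mismatches=1)
        assert (p.transcript_id, p.start, p.mismatches) == ("t1", 7, 1)

    def test_reverse_complement_hits_minus_strand(self, refs):
        p = ligation.map_clipped(reverse_complement("GGTTCAGGCATTACG"), refs)
        assert p.strand == "-" and p.start == 7

    def test_unmapped(self, refs):
        p, reason = ligation.map_clipped("N" * 20, refs, with_reason=True)
        assert p is None and reason == "unmapped"


class TestCallLigationSite:
    def test_printed_35mer_fragment(self):
        """A read built from the tRNA-Glu anticodon stem-loop 35-mer plus
        four arbitrary bases and the adapter core maps to a transcript
        beginning with that fragment with junction 35."""
        fragment = rna_to_dna(synth.TRNA_GLU_35MER)
        transcript = TranscriptRecord("tRNA_Glu", fragment + "GCGCCTTTTGGCT", "tRNA")
        read = fragment + "ATCG" + CORE
        events, discarded = ligation.call_events([("r1", read)], [transcript])
        assert not discarded
        assert len(events) == 1 and events[0].junction == 35

    def test_printed_17mer_fragment(self):
        fragment = rna_to_dna(synth.TRNA_GLU_17MER)
        transcript = TranscriptRecord(
            "tRNA_Glu", rna_to_dna(synth.TRNA_GLU_35MER) + "GCGCCTTTTGGCT", "tRNA"
        )
        read = fragment + "GGAA" + CORE
        events, _ = ligation.call_events([("r1", read)], [transcript])
        assert len(events) == 1 and events[0].junction == 17

    def test_junction_arithmetic(self):
        p = ligation.Placement("t", 11, "+", 0)
        assert ligation.call_ligation_site(p, 5).junction == 15

    def test_antisense_rejected(self):
        p = ligation.Placement("t", 11, "-", 0)
        with pytest.raises(ValueError, match="antisense"):
            ligation.call_ligation_site(p, 5)


class TestAggregate:
    @pytest.fixture()
    def toy(self):
        transcripts = [
            TranscriptRecord("g", "ACGT" * 25, "CDS"),
            TranscriptRecord("h", "ACGT" * 25, "CDS"),
        ]
        events = [
            LigationEvent("r1", "g", 10, random_bases="AAAA"),
            LigationEvent("r2", "g", 20, random_bases="CCCC"),
            LigationEvent("r3", "g", 20, random_bases="CCCC"),
            LigationEvent("r4", "h", 50, random_bases="GGGG"),
        ]
        return transcripts, events

    def test_per_gene_counts(self, toy):
        transcripts, events = toy
        gene, _ = ligation.aggregate_events(events, transcripts)
        assert dict(zip(gene["transcript_id"], gene["n_events"])) == {"g": 3, "h": 1}
        assert len(gene) == 2  # distinct targets

    def test_event_conservation(self, toy):
        transcripts, events = toy
        gene, _ = ligation.aggregate_events(events, transcripts)
        assert gene["n_events"].sum() == len(events)

    def test_inclusive_domain_bounds(self, toy):
        transcripts, events = toy
        domains = [DomainAnnotation("g", "D", 10, 20)]
        _, dom = ligation.aggregate_events(events, transcripts, domains)
        assert dom.loc[0, "observed"] == 3  # junctions at 10, 20, 20

    def test_overlapping_domains_count_in_each(self, toy):
        transcripts, events = toy
        domains = [
            DomainAnnotation("g", "PK3", 15, 25),
            DomainAnnotation("g", "H-overlap", 18, 22),
        ]
        gene, dom = ligation.aggregate_events(events, transcripts, domains)
        by_name = dict(zip(dom["domain"], dom["observed"]))
        assert by_name == {"PK3": 2, "H-overlap": 2}
        assert gene.loc[gene["transcript_id"] == "g", "n_events"].item() == 3

    def test_dedup_collapses_umi_duplicates(self, toy):
        transcripts, events = toy
        gene, _ = ligation.aggregate_events(events, transcripts, dedup=True)
        assert dict(zip(gene["transcript_id"], gene["n_events"])) == {"g": 2, "h": 1}

    def test_unknown_transcript_errors(self, toy):
        transcripts, _ = toy
        with pytest.raises(ValueError, match="unknown transcript"):
            ligation.aggregate_events([LigationEvent("r", "zz", 1)], transcripts)


class TestDomainEnrichment:
    def test_closed_form_extreme(self):
        """10/10 events in a 10% domain: p = 0.1^10."""
        import pandas as pd

        table = pd.DataFrame(
            [("t", "D", 1, 10, 10, 10)],
            columns=["transcript_id", "domain", "start", "end", "observed", "total"],
        )
        enr = ligation.domain_enrichment(table, {"t": 100})
        assert enr["p_value"].item() == pytest.approx(1e-10, rel=1e-9)
        assert enr["p_value"].item() == pytest.approx(
            binom_tail_enum(10, 10, 0.1), rel=1e-12
        )

    def test_whole_transcript_domain_is_certain(self):
        import pandas as pd

        table = pd.DataFrame(
            [("t", "ALL", 1, 100, 7, 7)],
            columns=["transcript_id", "domain", "start", "end", "observed", "total"],
        )
        enr = ligation.domain_enrichment(table, {"t": 100})
        assert enr["p_value"].item() == pytest.approx(1.0)

    def test_domain_longer_than_transcript_errors(self):
        import pandas as pd

        table = pd.DataFrame(
            [("t", "D", 1, 200, 1, 1)],
            columns=["transcript_id", "domain", "start", "end", "observed", "total"],
        )
        with pytest.raises(ValueError, match="longer than"):
            ligation.domain_enrichment(table, {"t": 100})

    def test_null_calibration(self):
        """Uniform junctions: the domain test rejects at ~alpha."""
        rng = np.random.default_rng(77)
        n, p0, reps = 500, 0.3, 2000
        counts = rng.binomial(n, p0, size=reps)
        from rtcseq.stats import binom_upper_tail

        pvals = np.array([binom_upper_tail(int(k), n, p0) for k in counts])
        rate = float((pvals <= 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se


class TestComposition:
    def _events_on(self, transcript, junctions):
        return [
            LigationEvent(f"r{i}", transcript.id, j, random_bases="ACGT")
            for i, j in enumerate(junctions)
        ]

    def test_fixed_flank_base_has_full_information(self):
        t = TranscriptRecord("t", "A" * 50, "CDS")
        comp = ligation.junction_composition(self._events_on(t, [10, 20, 30]), [t], flank=3)
        assert comp.target_freq.loc["A"].tolist() == [1.0, 1.0, 1.0]
        assert comp.target_info.tolist() == pytest.approx([2.0, 2.0, 2.0])

    def test_columns_sum_to_one(self, small_transcriptome):
        transcripts, _ = small_transcriptome
        t = transcripts[0]
        comp = ligation.junction_composition(
            self._events_on(t, list(range(10, 40))), [t], flank=5
        )
        np.testing.assert_allclose(comp.target_freq.sum(axis=0), 1.0)
        np.testing.assert_allclose(comp.adapter_freq.sum(axis=0), 1.0)

    def test_uniform_random_bases_carry_no_information(self):
        t = TranscriptRecord("t", "A" * 2000, "CDS")
        rng = np.random.default_rng(5)
        events = [
            LigationEvent(
                f"r{i}", "t", 100,
                random_bases="".join(rng.choice(list("ACGT"), size=4)),
            )
            for i in range(2000)
        ]
        comp = ligation.junction_composition(events, [t], flank=2)
        assert np.all(comp.adapter_info.to_numpy() < 0.01)

    def test_no_events_errors(self):
        t = TranscriptRecord("t", "A" * 50, "CDS")
        with pytest.raises(ValueError, match="no events"):
            ligation.junction_composition([], [t])


class TestSamReader:
    def test_forward_and_reverse_records(self, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:t1\tLN:100\n"
            "r1\t0\tt1\t11\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\n"
            "r2\t16\tt1\t11\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t*\tNM:i:0\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 20 + "\t*\n"
        )
        t = TranscriptRecord("t1", "A" * 100, "CDS")
        events, discarded = ligation.events_from_sam(str(sam), [t])
        assert len(events) == 1
        assert events[0].junction == 30  # start 11 + 20 aligned bases - 1
        assert discarded["antisense"] == 1 and discarded["unmapped"] == 1


class TestEndToEnd:
    def test_full_recovery_and_specificity(self, small_transcriptome):
        """Every usable adapter read yields an event at the truth
        position; background reads yield none."""
        transcripts, domains = small_transcriptome
        rng = np.random.default_rng(13)
        sites = [
            (t.id, int(rng.integers(30, t.length + 1))) for t in transcripts[:15]
        ]
        rs = synth.gen_ligated_reads(
            transcripts, sites, n_reads=2000, frac_with_adapter=0.6,
            read_len=75, seed=21,
        )
        res = ligation.LigationModel(rs.reads, transcripts, domains).fit()
        ev = res.events_frame().merge(rs.truth, on="read_id", suffixes=("", "_true"))
        assert len(ev) == int(rs.truth["has_adapter"].sum())
        assert (ev["junction"] == ev["junction_true"]).all()
        assert (ev["transcript_id"] == ev["transcript_id_true"]).all()
        assert not ev.merge(
            rs.truth[~rs.truth["has_adapter"]], on="read_id"
        ).shape[0]
        # conservation: gene table sums to accepted events
        assert res.gene_table["n_events"].sum() == res.n_events
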