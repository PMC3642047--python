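"""Event-detection tests: CE/CSE/RI/ALT calls on constructed transcript
pairs, reliability filters, counting policies."""

import pytest

from estforge.align import SplicedAlignment
from estforge.clustermerge import ESTGene, ESTTranscript
from estforge.splice_events import (
    FilterSpec, PAPER_LITERAL_SITES, SpliceEvent, apply_filters,
    count_events, detect_events,
)


def transcript(tid, exons):
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    return ESTTranscript(tid, "c1", strand="+", exons=list(exons),
                         introns=introns, supporting_est_ids={tid})


def gene_of(*transcripts):
    lo = min(t.span[0] for t in transcripts)
    hi = max(t.span[1] for t in transcripts)
    return (ESTGene("g1", "c1", "+", [t.id for t in transcripts], (lo, hi)),
            {t.id: t for t in transcripts})


EXONS = [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]


class TestDetect:
    def test_single_transcript_gene_has_no_events(self):
        g, ts = gene_of(transcript("a", EXONS))
        assert detect_events(g, ts) == []

    def test_cassette_exon(self):
        incl = transcript("i", EXONS[:3])
        excl = transcript("x", [EXONS[0], EXONS[2]])
        g, ts = gene_of(incl, excl)
        evs = detect_events(g, ts)
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.event_type, ev.coordinates, ev.exon_count) == \
            ("CE", (200, 300), 1)
        assert ev.inclusion_transcripts == {"i"}
        assert ev.exclusion_transcripts == {"x"}

    def test_eleven_exon_cse_stretch(self):
        exons = [(i * 200, i * 200 + 100) for i in range(13)]
        incl = transcript("i", exons)
        excl = transcript("x", [exons[0], exons[12]])
        g, ts = gene_of(incl, excl)
        evs = detect_events(g, ts)
        assert [(e.event_type, e.exon_count) for e in evs] == [("CSE", 11)]
        assert evs[0].coordinates == (exons[1][0], exons[11][1])

    def test_retained_intron(self):
        spliced = transcript("s", EXONS[:3])
        retained = transcript("r", [EXONS[0], (200, 500)])
        g, ts = gene_of(spliced, retained)
        evs = detect_events(g, ts)
        assert [(e.event_type, e.coordinates) for e in evs] == \
            [("RI", (300, 400))]
        assert evs[0].inclusion_transcripts == {"r"}

    def test_alt_donor_and_acceptor(self):
        base = transcript("a", [(0, 100), (200, 300)])
        alt_donor = transcript("d", [(0, 120), (200, 300)])
        alt_acceptor = transcript("c", [(0, 100), (220, 300)])
        g, ts = gene_of(base, alt_donor)
        assert [(e.event_type, e.coordinates) for e in detect_events(g, ts)] \
            == [("ALT5", (100, 120))]
        g, ts = gene_of(base, alt_acceptor)
        assert [(e.event_type, e.coordinates) for e in detect_events(g, ts)] \
            == [("ALT3", (200, 220))]

    def test_alt_types_flip_on_minus_strand(self):
        base = transcript("a", [(0, 100), (200, 300)])
        alt = transcript("d", [(0, 120), (200, 300)])
        g, ts = gene_of(base, alt)
        g.strand = "-"
        assert detect_events(g, ts)[0].event_type == "ALT3"

    def test_duplicate_events_reported_once(self):
        incl1 = transcript("i1", EXONS[:3])
        incl2 = transcript("i2", EXONS[:4])
        excl = transcript("x", [EXONS[0], EXONS[2], EXONS[3]])
        g, ts = gene_of(incl1, incl2, excl)
        ce = [e for e in detect_events(g, ts) if e.event_type == "CE"]
        assert len(ce) == 1
        assert ce[0].inclusion_transcripts >= {"i1", "i2"}

    def test_events_stay_inside_gene_span(self, study):
        by_gene = {g.id: g for g in study.genes}
        for ev in study.events:
            lo, hi = by_gene[ev.gene_id].span
            assert lo <= ev.coordinates[0] < ev.coordinates[1] <= hi


def support_aln(est_id, exons, mism=(), indels=(), sites="GT-AG"):
    blocks, introns, off = [], [], 0
    d, a = sites.split("-")
    for i, (s, e) in enumerate(exons):
        blocks.append(((s, e), (off, off + e - s)))
        off += e - s
        if i + 1 < len(exons):
            introns.append((e, exons[i + 1][0], d, a))
    return SplicedAlignment(est_id=est_id, contig="c1", blocks=blocks,
                            mismatch_positions=list(mism),
                            indel_runs=list(indels), introns=introns,
                            identity=1.0, est_coverage=1.0, est_length=off)


class TestFilters:
    def _event(self):
        return SpliceEvent("CE", "g1", (200, 300),
                           inclusion_transcripts={"i"},
                           exclusion_transcripts={"x"})

    def test_clean_support_passes_all_filters(self):
        ev = self._event()
        support = {"i": [support_aln("a", EXONS[:3])],
                   "x": [support_aln("b", [EXONS[0], EXONS[2]])]}
        apply_filters(ev, support)
        assert ev.canonical_sites and ev.indel_ok and ev.flank_matches
        assert ev.reliable

    def test_noncanonical_junction_fails_site_filter(self):
        ev = self._event()
        support = {"i": [support_aln("a", EXONS[:3], sites="CT-AC")],
                   "x": []}
        apply_filters(ev, support)  # forward CT..AC on a + gene: not canonical
        assert not ev.canonical_sites

    def test_minus_strand_dinucleotides_oriented(self):
        ev = self._event()
        support = {"i": [support_aln("a", EXONS[:3], sites="CT-AC")],
                   "x": []}
        apply_filters(ev, support, strand="-")
        assert ev.canonical_sites

    def test_paper_literal_site_preset(self):
        ev = self._event()
        support = {"i": [support_aln("a", EXONS[:3], sites="GC-AG")], "x": []}
        apply_filters(ev, support,
                      FilterSpec(canonical_site_set=PAPER_LITERAL_SITES))
        assert not ev.canonical_sites  # GC:AG absent from the literal preset
        apply_filters(ev, support)
        assert ev.canonical_sites  # standard preset includes GC:AG

    def test_nine_base_indel_run_is_excluded(self):
        ev = self._event()
        ok = {"i": [support_aln("a", EXONS[:3], indels=[(50, 8, "ins")])],
              "x": []}
        apply_filters(ev, ok)
        assert ev.indel_ok
        bad = {"i": [support_aln("a", EXONS[:3], indels=[(50, 9, "ins")])],
               "x": []}
        apply_filters(ev, bad)
        assert not ev.indel_ok  # "shorter than 9" is an exclusive bound

    def test_mismatch_at_boundary_fails_flank_filter(self):
        ev = self._event()
        # EST offset of genome 200 in the inclusion alignment is 100; a
        # mismatch there breaks the three-exact-match flank
        support = {"i": [support_aln("a", EXONS[:3], mism=[101])], "x": []}
        apply_filters(ev, support)
        assert not ev.flank_matches
        support = {"i": [support_aln("a", EXONS[:3], mism=[150])], "x": []}
        apply_filters(ev, support)
        assert ev.flank_matches

    def test_relaxing_filters_never_shrinks_reliable_set(self, study):
        strict = FilterSpec(max_indel_run=5, min_flank_matches=5)
        loose = FilterSpec(max_indel_run=20, min_flank_matches=1)
        aln_by_est = study.aln_by_est()
        n_strict = n_loose = 0
        for g in study.genes:
            support = {
                tid: [a for est in study.t_by_id[tid].supporting_est_ids
                      for a in aln_by_est[est]]
                for tid in g.member_transcript_ids}
            for ev in detect_events(g, study.t_by_id):
                s = apply_filters(
                    SpliceEvent(ev.event_type, ev.gene_id, ev.coordinates,
                                ev.exon_count, ev.inclusion_transcripts,
                                ev.exclusion_transcripts),
                    support, strict, strand=g.strand).reliable
                l = apply_filters(ev, support, loose, strand=g.strand).reliable
                n_strict += s
                n_loose += l
                assert l or not s  # strict-reliable implies loose-reliable
        assert n_loose >= n_strict


class TestCounting:
    def test_gene_and_exon_levels(self):
        evs = [
            SpliceEvent("CE", "g1", (0, 1), 1, canonical_sites=True,
                        indel_ok=True, flank_matches=True),
            SpliceEvent("CSE", "g1", (2, 3), 11, canonical_sites=True,
                        indel_ok=True, flank_matches=True),
            SpliceEvent("RI", "g2", (4, 5), 1, canonical_sites=True,
                        indel_ok=True, flank_matches=True),
            SpliceEvent("CE", "g2", (6, 7), 1),  # unreliable: not counted
        ]
        assert count_events(evs, "gene") == {"CE": 1, "CSE": 1, "RI": 1}
        assert count_events(evs, "exon") == {"CE": 1, "CSE": 11, "RI": 1}
        with pytest.raises(ValueError):
            count_events(evs, "transcript")

    def test_published_exon_tally(self):
        """One 11-exon stretch plus 15 singles -> 26 skipped exons."""
        evs = [SpliceEvent("CSE", "g0", (0, 1), 11, canonical_sites=True,
                           indel_ok=True, flank_matches=True)]
        evs += [SpliceEvent("CE", f"g{i+1}", (i, i + 1), 1,
                            canonical_sites=True, indel_ok=True,
                            flank_matches=True) for i in range(15)]
        exon = count_events(evs, "exon")
        assert exon["CE"] + exon["CSE"] == 26

    def test_counts_match_registry_tally(self, study):
        """Reliable-event counts equal a brute tally over matched planted
        events."""
        from collections import Counter
        planted = {(e.event_type, e.coordinates): e
                   for e in study.truth.event_registry}
        matched = [planted[(e.event_type, e.coordinates)]
                   for e in study.events
                   if e.reliable and (e.event_type, e.coordinates) in planted]
        brute_gene = Counter()
        seen = set()
        for ev in matched:
            if (ev.event_type, ev.gene_id) not in seen:
                seen.add((ev.event_type, ev.gene_id))
                brute_gene[ev.event_type] += 1
        reliable_matched = [
            e for e in study.events
            if e.reliable and (e.event_type, e.coordinates) in planted]
        assert count_events(reliable_matched, "gene") == dict(brute_gene)
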