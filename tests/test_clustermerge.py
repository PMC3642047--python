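"""Cluster-and-merge tests: overlap clustering, the compatibility rule,
greedy merging, unspliced attachment, strand inference and gene grouping."""

import numpy as np
import pytest

from estforge.align import SplicedAlignment
from estforge.clustermerge import (
    ESTTranscript, attach_unspliced, build_transcripts, cluster_loci,
    group_estgenes, infer_strand, merge_cluster, splice_compatible,
)


def aln(est_id, blocks, contig="c1"):
    """Alignment from genome exon blocks; EST intervals derived."""
    out_blocks, introns, off = [], [], 0
    for i, (s, e) in enumerate(blocks):
        out_blocks.append(((s, e), (off, off + e - s)))
        off += e - s
        if i + 1 < len(blocks):
            introns.append((e, blocks[i + 1][0], "GT", "AG"))
    return SplicedAlignment(est_id=est_id, contig=contig, blocks=out_blocks,
                            introns=introns, identity=1.0, est_coverage=1.0,
                            est_length=off)


class TestClusterLoci:
    def test_disjoint_spans_split(self):
        a, b = aln("a", [(0, 100)]), aln("b", [(200, 300)])
        assert [len(c) for c in cluster_loci([a, b])] == [1, 1]

    def test_transitive_chaining(self):
        a = aln("a", [(0, 120)])
        b = aln("b", [(100, 260)])
        c = aln("c", [(250, 400)])
        clusters = cluster_loci([c, a, b])
        assert len(clusters) == 1
        assert {x.est_id for x in clusters[0]} == {"a", "b", "c"}

    def test_matches_graph_components_oracle(self):
        """Cluster count equals connected components of the interval-overlap
        graph (networkx oracle on random intervals)."""
        import networkx as nx
        rng = np.random.default_rng(5)
        for _ in range(20):
            spans = [(int(s), int(s + rng.integers(10, 200)))
                     for s in rng.integers(0, 2000, 30)]
            alns = [aln(f"r{i}", [sp]) for i, sp in enumerate(spans)]
            G = nx.Graph()
            G.add_nodes_from(range(len(spans)))
            for i in range(len(spans)):
                for j in range(i + 1, len(spans)):
                    if spans[i][0] < spans[j][1] and spans[j][0] < spans[i][1]:
                        G.add_edge(i, j)
            assert len(cluster_loci(alns)) == \
                nx.number_connected_components(G)


class TestSpliceCompatible:
    def test_shared_intron_staggered_ends(self):
        a = aln("a", [(0, 100), (200, 300)])
        b = aln("b", [(50, 100), (200, 350)])
        assert splice_compatible(a, b)

    def test_skipped_exon_conflict_blocks_merge(self):
        # a skips the exon (150, 180) that b contains
        a = aln("a", [(0, 100), (200, 300)])
        b = aln("b", [(0, 100), (150, 180), (200, 300)])
        assert not splice_compatible(a, b)
        assert not splice_compatible(b, a)

    def test_no_shared_intron_no_merge(self):
        a = aln("a", [(0, 100), (200, 300)])
        b = aln("b", [(250, 400), (500, 600)])
        assert not splice_compatible(a, b)

    def test_unspliced_input_is_contract_violation(self):
        with pytest.raises(ValueError):
            splice_compatible(aln("a", [(0, 100)]),
                              aln("b", [(0, 100), (200, 300)]))


class TestMergeCluster:
    def test_tiling_reads_build_single_transcript(self):
        exons = [(0, 100), (200, 300), (400, 500), (600, 700)]
        reads = [aln("a", exons[:3]), aln("b", exons[1:4]),
                 aln("c", exons[2:])]
        out = merge_cluster(reads)
        assert len(out) == 1
        assert out[0].exons == exons
        assert out[0].supporting_est_ids == {"a", "b", "c"}

    def test_skipped_exon_isoforms_stay_separate(self):
        incl = aln("i", [(0, 100), (200, 300), (400, 500)])
        excl = aln("x", [(0, 100), (400, 500)])
        out = merge_cluster([incl, excl])
        assert len(out) == 2

    def test_structure_completion_extends_compatible_transcripts(self):
        """A read shared between isoforms supports one transcript but
        completes the structure of every compatible one."""
        # exons A(0,100) B(200,300) C(400,500) D(600,700) E(800,900);
        # the exclusion isoform skips D with the intron (500, 800)
        full = aln("i", [(0, 100), (200, 300), (400, 500), (600, 700),
                         (800, 900)])
        excl = aln("x", [(200, 300), (400, 500), (800, 900)])
        shared = aln("s", [(0, 100), (200, 300), (400, 500)])
        out = merge_cluster([full, excl, shared])
        assert len(out) == 2
        skipping = next(t for t in out if (500, 800) in t.introns)
        # structure completion propagated the 5' junction from the shared
        # read even though that read supports the other transcript
        assert (100, 200) in skipping.introns
        assert skipping.exons[0] == (0, 100)
        assert "s" not in skipping.supporting_est_ids
        supports = [t.supporting_est_ids for t in out]
        assert sum("s" in s for s in supports) == 1  # support stays unique


class TestAttachUnspliced:
    TR = lambda self: ESTTranscript(
        id="t1", contig="c1", exons=[(0, 100), (200, 300), (400, 500)],
        introns=[(100, 200), (300, 400)], supporting_est_ids={"seed"})

    def test_absorbed_inside_internal_exon(self):
        t = self.TR()
        _, singles = attach_unspliced([t], [aln("u", [(220, 280)])])
        assert singles == []
        assert "u" in t.supporting_est_ids
        assert t.exons[1] == (200, 300)

    def test_terminal_exon_extended_outward(self):
        t = self.TR()
        attach_unspliced([t], [aln("u", [(430, 520)])])
        assert t.exons[-1] == (400, 520)

    def test_mostly_outside_read_not_absorbed(self):
        t = self.TR()
        _, singles = attach_unspliced([t], [aln("u", [(480, 700)])])
        assert "u" not in t.supporting_est_ids
        assert len(singles) == 1

    def test_intron_spanning_read_becomes_single_exon_leftover(self):
        t = self.TR()
        _, singles = attach_unspliced([t], [aln("u", [(80, 220)])])
        assert "u" not in t.supporting_est_ids
        assert len(singles) == 1
        assert singles[0].strand == "unknown"
        assert singles[0].exons == [(80, 220)]

    def test_decisions_match_containment_oracle(self, study):
        unspliced = [a for a in study.kept if not a.spliced][:1000]
        spliced_ts = [t for t in study.transcripts if t.spliced]
        housed = {e for t in spliced_ts for e in t.supporting_est_ids}
        for a in unspliced:
            s, e = a.span
            max_over = int(0.25 * (e - s))
            could = False
            for t in spliced_ts:
                if t.contig != a.contig:
                    continue
                if any(s < ie and i0 < e for i0, ie in t.introns):
                    continue
                for idx, (xs, xe) in enumerate(t.exons):
                    lo = xs - (max_over if idx == 0 else 0)
                    hi = xe + (max_over if idx == len(t.exons) - 1 else 0)
                    if s >= lo and e <= hi and s < xe and xs < e:
                        could = True
            assert (a.est_id in housed) == could


class TestStrandAndGrouping:
    def test_infer_strand_consensus(self):
        contigs = {"c": "ccGTxxxxAGccCTxxxxACcc".upper()}
        plus = ESTTranscript("t", "c", exons=[(0, 2), (10, 12)],
                             introns=[(2, 10)], supporting_est_ids={"x"})
        minus = ESTTranscript("t", "c", exons=[(10, 12), (20, 22)],
                              introns=[(12, 20)], supporting_est_ids={"x"})
        assert infer_strand(plus, contigs) == "+"
        assert infer_strand(minus, contigs) == "-"
        mixed = ESTTranscript("t", "c", exons=[(0, 2), (10, 12), (20, 22)],
                              introns=[(2, 10), (12, 20)],
                              supporting_est_ids={"x"})
        assert infer_strand(mixed, contigs) == "unknown"
        no_introns = ESTTranscript("t", "c", exons=[(0, 22)],
                                   supporting_est_ids={"x"})
        assert infer_strand(no_introns, contigs) == "unknown"

    def _t(self, tid, span, strand):
        return ESTTranscript(tid, "c1", strand=strand, exons=[span],
                             supporting_est_ids={tid})

    def test_incompatible_same_strand_transcripts_share_gene(self):
        genes = group_estgenes([self._t("a", (0, 500), "+"),
                                self._t("b", (300, 900), "+")])
        assert len(genes) == 1
        assert set(genes[0].member_transcript_ids) == {"a", "b"}
        assert genes[0].span == (0, 900)

    def test_opposite_strands_never_grouped(self):
        genes = group_estgenes([self._t("a", (0, 500), "+"),
                                self._t("b", (300, 900), "-")])
        assert len(genes) == 2

    def test_unknown_strand_never_bridges(self):
        genes = group_estgenes([
            self._t("a", (0, 500), "+"), self._t("u", (400, 700), "unknown"),
            self._t("b", (600, 900), "+")])
        spans = sorted(tuple(g.member_transcript_ids) for g in genes)
        assert spans == [("a",), ("b",), ("u",)]

    def test_grouping_matches_graph_oracle(self, study):
        import networkx as nx
        known = [t for t in study.transcripts if t.strand in "+-"]
        G = nx.Graph()
        G.add_nodes_from(t.id for t in known)
        for i, t in enumerate(known):
            for u in known[i + 1:]:
                if (t.contig == u.contig and t.strand == u.strand
                        and t.span[0] < u.span[1] and u.span[0] < t.span[1]):
                    G.add_edge(t.id, u.id)
        expected = {frozenset(c) for c in nx.connected_components(G)}
        got = {frozenset(g.member_transcript_ids) for g in study.genes
               if g.strand in "+-"}
        assert got == expected


def test_support_conservation(study):
    """Every kept alignment supports exactly one transcript."""
    seen = {}
    for t in study.transcripts:
        for est in t.supporting_est_ids:
            assert est not in seen, f"{est} in {seen[est]} and {t.id}"
            seen[est] = t.id
    assert set(seen) == {a.est_id for a in study.kept}


def test_no_intron_conflicts_within_transcripts(study):
    """Post-hoc audit: no two spliced alignments supporting one transcript
    disagree on the intron structure of the region they both cover.  (Full
    pairwise compatibility additionally demands a shared junction, which
    members linked through an intermediary need not have.)"""
    import itertools
    by_est = {}
    for a in study.kept:
        by_est.setdefault(a.est_id, a)
    checked = 0
    for t in study.transcripts:
        members = [by_est[e] for e in t.supporting_est_ids
                   if by_est[e].spliced]
        for a, b in itertools.islice(itertools.combinations(members, 2), 200):
            lo = max(a.span[0], b.span[0])
            hi = min(a.span[1], b.span[1])
            if lo >= hi:
                continue
            ia = {i for i in ((s, e) for s, e, _, _ in a.introns)
                  if i[0] < hi and i[1] > lo}
            ib = {i for i in ((s, e) for s, e, _, _ in b.introns)
                  if i[0] < hi and i[1] > lo}
            assert ia == ib
            checked += 1
    assert checked > 1000
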