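"""Genome-based cluster-and-merge transcript reconstruction.

EST-genome alignments are clustered by genomic overlap, spliced alignments
sharing compatible splicing structures are merged into non-redundant
ESTTranscripts, unspliced alignments are housed by exon containment, and
overlapping same-strand transcripts are grouped into ESTGenes.  Two spliced
alignments are merge-compatible iff they share at least one intron with
exactly matching donor and acceptor coordinates and their intron sets agree
over the genomic region both cover (a skipped exon present in only one of
them blocks the merge).  Transcript strand is inferred from the junction
consensus: GT..AG read on the forward strand means '+', CT..AC means '-'.

Merging is deterministic greedy agglomeration to a fixpoint: alignments are
processed by descending intron count, then descending genomic span, then
id, and a candidate joins a transcript only if compatible with the merged
structure, which makes the outcome invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import SplicedAlignment

__all__ = [
    "ESTTranscript",
    "ESTGene",
    "cluster_loci",
    "splice_compatible",
    "merge_cluster",
    "attach_unspliced",
    "infer_strand",
    "group_estgenes",
    "build_transcripts",
]


@dataclass
class ESTTranscript:
    """A non-redundant merged splice structure supported by >= 1 EST."""

    id: str
    contig: str
    strand: str = "unknown"
    exons: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)
    supporting_est_ids: set[str] = field(default_factory=set)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced(self) -> bool:
        return bool(self.introns)


@dataclass
class ESTGene:
    """Overlapping same-strand ESTTranscripts at one locus."""

    id: str
    contig: str
    strand: str
    member_transcript_ids: list[str]
    span: tuple[int, int]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def cluster_loci(alignments: list[SplicedAlignment]
                 ) -> list[list[SplicedAlignment]]:
    """Connected components of genomic-span overlap, per contig."""
    clusters: list[list[SplicedAlignment]] = []
    by_contig: dict[str, list[SplicedAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig, []).append(a)
    for cid in sorted(by_contig):
        alns = sorted(by_contig[cid], key=lambda a: (a.span, a.est_id))
        cur: list[SplicedAlignment] = []
        cur_end = -1
        for a in alns:
            s, e = a.span
            if cur and s >= cur_end:
                clusters.append(cur)
                cur = []
            cur.append(a)
            cur_end = max(cur_end, e)
        if cur:
            clusters.append(cur)
    return clusters


def _intron_conflict(introns_a, introns_b, lo: int, hi: int) -> bool:
    """True if the intron sets differ over the shared region [lo, hi)."""
    in_a = {i for i in introns_a if i[0] < hi and i[1] > lo}
    in_b = {i for i in introns_b if i[0] < hi and i[1] > lo}
    return in_a != in_b


def splice_compatible(a: SplicedAlignment, b: SplicedAlignment) -> bool:
    """Merge rule for two spliced alignments on the same contig."""
    if not a.spliced or not b.spliced:
        raise ValueError("splice_compatible requires spliced alignments; "
                         "unspliced alignments are handled by attach_unspliced")
    if a.contig != b.contig:
        return False
    ia = [(s, e) for s, e, _, _ in a.introns]
    ib = [(s, e) for s, e, _, _ in b.introns]
    if not set(ia) & set(ib):
        return False
    lo = max(a.span[0], b.span[0])
    hi = min(a.span[1], b.span[1])
    if lo >= hi:
        return False
    return not _intron_conflict(ia, ib, lo, hi)


def _compatible_with_transcript(t: ESTTranscript, introns, span) -> bool:
    if not set(t.introns) & set(introns):
        return False
    lo = max(t.span[0], span[0])
    hi = min(t.span[1], span[1])
    if lo >= hi:
        return False
    return not _intron_conflict(t.introns, introns, lo, hi)


def merge_cluster(cluster: list[SplicedAlignment], id_start: int = 1,
                  prefix: str = "ESTT") -> list[ESTTranscript]:
    """Greedy agglomeration of the cluster's spliced alignments.

    Deterministic processing order: descending intron count, descending
    genomic span length, then est id.  A candidate joins the first existing
    transcript whose merged structure it is compatible with; transcripts are
    then pairwise re-merged to a fixpoint.
    """
    spliced = [a for a in cluster if a.spliced]
    order = sorted(
        spliced,
        key=lambda a: (-len(a.introns), -(a.span[1] - a.span[0]), a.est_id))
    transcripts: list[ESTTranscript] = []
    for a in order:
        ia = [(s, e) for s, e, _, _ in a.introns]
        home = None
        for t in transcripts:
            if _compatible_with_transcript(t, ia, a.span):
                home = t
                break
        if home is None:
            home = ESTTranscript(id="", contig=a.contig)
            transcripts.append(home)
        home.exons = _merge_intervals(home.exons + list(a.genome_blocks))
        home.introns = sorted(set(home.introns) | set(ia))
        home.supporting_est_ids.add(a.est_id)
        # merged exon union may bridge over what used to be uncovered gaps
        home.exons = _split_exons_at_introns(home.exons, home.introns)

    # alternate two fixpoints until stable: (i) merge transcripts that are
    # mutually compatible; (ii) structure completion — an alignment extends
    # the structure of every transcript it is compatible with, even though
    # it supports exactly one (shared reads witness both isoforms)
    outer = True
    while outer:
        outer = False
        changed = True
        while changed:
            changed = False
            for i in range(len(transcripts)):
                for j in range(i + 1, len(transcripts)):
                    t, u = transcripts[i], transcripts[j]
                    if _compatible_with_transcript(t, u.introns, u.span):
                        t.exons = _split_exons_at_introns(
                            _merge_intervals(t.exons + u.exons),
                            sorted(set(t.introns) | set(u.introns)))
                        t.introns = sorted(set(t.introns) | set(u.introns))
                        t.supporting_est_ids |= u.supporting_est_ids
                        del transcripts[j]
                        changed = outer = True
                        break
                if changed:
                    break
        changed = True
        while changed:
            changed = False
            for a in order:
                ia = [(s, e) for s, e, _, _ in a.introns]
                for t in transcripts:
                    if not _compatible_with_transcript(t, ia, a.span):
                        continue
                    new_introns = sorted(set(t.introns) | set(ia))
                    new_exons = _split_exons_at_introns(
                        _merge_intervals(t.exons + list(a.genome_blocks)),
                        new_introns)
                    if new_exons != t.exons or new_introns != t.introns:
                        t.exons, t.introns = new_exons, new_introns
                        changed = outer = True

    transcripts.sort(key=lambda t: (t.span, t.introns[0] if t.introns else (0, 0)))
    for n, t in enumerate(transcripts):
        t.id = f"{prefix}{id_start + n:05d}"
    return transcripts


def _split_exons_at_introns(exons, introns):
    """Exon union minus the intron intervals (introns stay introns even if
    staggered members tile across them)."""
    out = []
    for s, e in exons:
        cuts = [s]
        for a, b in introns:
            if s < b and a < e:
                cuts.extend([max(a, s), min(b, e)])
        cuts.append(e)
        cuts = sorted(set(cuts))
        inside = False
        for x, y in zip(cuts, cuts[1:]):
            mid = (x + y) / 2.0
            inside = any(a <= mid < b for a, b in introns)
            if not inside and y > x:
                out.append((x, y))
    return _merge_intervals(out)


def attach_unspliced(transcripts: list[ESTTranscript],
                     unspliced: list[SplicedAlignment],
                     id_start: int = 1, prefix: str = "ESTT",
                     extend_terminal: bool = True,
                     max_overhang_fraction: float = 0.25
                     ) -> tuple[list[ESTTranscript], list[ESTTranscript]]:
    """House unspliced alignments.

    An unspliced alignment joins a spliced transcript iff its span lies
    within one exon; terminal exons extend outward past the transcript
    ends, but only for reads that mostly lie inside (overhang at most
    ``max_overhang_fraction`` of the read span — a read mostly outside the
    transcript is weak evidence of belonging to it).  Leftovers are merged
    among themselves by genomic overlap into single-exon transcripts of
    unknown strand.
    """
    leftovers: list[SplicedAlignment] = []
    for a in sorted(unspliced, key=lambda x: (x.span, x.est_id)):
        s, e = a.span
        max_over = int(max_overhang_fraction * (e - s))
        home = None
        for t in transcripts:
            if t.contig != a.contig or not t.spliced:
                continue
            if any(s < ie and istart < e for istart, ie in t.introns):
                continue  # spans an intron: not contained in one exon
            inside = False
            n_ex = len(t.exons)
            for idx, (xs, xe) in enumerate(t.exons):
                left_ok = s >= xs or (
                    extend_terminal and idx == 0 and xs - s <= max_over)
                right_ok = e <= xe or (
                    extend_terminal and idx == n_ex - 1
                    and e - xe <= max_over)
                if left_ok and right_ok and s < xe and xs < e:
                    inside = True
                    break
            if inside:
                home = t
                break
        if home is None:
            leftovers.append(a)
            continue
        if extend_terminal:
            first, last = home.exons[0], home.exons[-1]
            if s < first[0] and e > first[0]:
                home.exons[0] = (s, first[1])
            if e > last[1] and s < last[1]:
                home.exons[-1] = (last[0], e)
        home.supporting_est_ids.add(a.est_id)

    singles: list[ESTTranscript] = []
    for a in sorted(leftovers, key=lambda x: (x.contig, x.span, x.est_id)):
        s, e = a.span
        if (singles and singles[-1].contig == a.contig
                and s < singles[-1].exons[0][1]):
            t = singles[-1]
            t.exons = [(t.exons[0][0], max(t.exons[0][1], e))]
            t.supporting_est_ids.add(a.est_id)
        else:
            singles.append(ESTTranscript(
                id="", contig=a.contig, strand="unknown", exons=[(s, e)],
                supporting_est_ids={a.est_id}))
    for n, t in enumerate(singles):
        t.id = f"{prefix}{id_start + n:05d}"
    return transcripts, singles


def infer_strand(transcript: ESTTranscript, contigs: dict[str, str]) -> str:
    """Junction-consensus strand call.

    '+' when every intron reads GT..AG on the forward strand, '-' when every
    intron reads CT..AC (GT..AG on the reverse), otherwise 'unknown'.
    """
    if not transcript.introns:
        return "unknown"
    genome = contigs[transcript.contig]
    dinucs = [(genome[s:s + 2], genome[e - 2:e]) for s, e in transcript.introns]
    if all(d == ("GT", "AG") for d in dinucs):
        return "+"
    if all(d == ("CT", "AC") for d in dinucs):
        return "-"
    return "unknown"


def group_estgenes(transcripts: list[ESTTranscript], id_start: int = 1,
                   prefix: str = "ESTG") -> list[ESTGene]:
    """Connected components of same-strand genomic overlap.

    Unknown-strand transcripts never bridge '+' and '-' loci: each forms its
    own single-member component.
    """
    genes: list[ESTGene] = []
    comp_members: list[list[ESTTranscript]] = []
    for strand in ("+", "-"):
        pool = sorted((t for t in transcripts if t.strand == strand),
                      key=lambda t: (t.contig, t.span, t.id))
        cur: list[ESTTranscript] = []
        cur_contig, cur_end = None, -1
        for t in pool:
            s, e = t.span
            if cur and (t.contig != cur_contig or s >= cur_end):
                comp_members.append(cur)
                cur = []
                cur_end = -1
            cur.append(t)
            cur_contig = t.contig
            cur_end = max(cur_end, e)
        if cur:
            comp_members.append(cur)
    for t in transcripts:
        if t.strand == "unknown":
            comp_members.append([t])
    comp_members.sort(key=lambda ms: (ms[0].contig, min(t.span[0] for t in ms),
                                      ms[0].id))
    for n, ms in enumerate(comp_members):
        span = (min(t.span[0] for t in ms), max(t.span[1] for t in ms))
        genes.append(ESTGene(
            id=f"{prefix}{id_start + n:05d}", contig=ms[0].contig,
            strand=ms[0].strand, member_transcript_ids=[t.id for t in ms],
            span=span))
    return genes


def build_transcripts(alignments: list[SplicedAlignment],
                      contigs: dict[str, str],
                      prefix_t: str = "ESTT", prefix_g: str = "ESTG"
                      ) -> tuple[list[ESTTranscript], list[ESTGene]]:
    """Full cluster -> merge -> attach -> strand -> group pipeline."""
    spliced = [a for a in alignments if a.spliced]
    unspliced = [a for a in alignments if not a.spliced]
    transcripts: list[ESTTranscript] = []
    nid = 1
    for cluster in cluster_loci(spliced):
        ts = merge_cluster(cluster, id_start=nid, prefix=prefix_t)
        nid += len(ts)
        transcripts.extend(ts)
    transcripts, singles = attach_unspliced(
        transcripts, unspliced, id_start=nid, prefix=prefix_t)
    transcripts = transcripts + singles
    for t in transcripts:
        if t.spliced:
            t.strand = infer_strand(t, contigs)
    genes = group_estgenes(transcripts, prefix=prefix_g)
    return transcripts, genes
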