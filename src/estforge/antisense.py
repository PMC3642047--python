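"""Sense / cis-natural-antisense pair (SCP) detection and classification.

An SCP is a pair of ESTGenes on opposite strands whose genomic spans
overlap; to guard against wrong strand calls, both members must carry at
least one canonical GT-AG splice junction.  Orientation classes: contained
(one span fully covers the other, evaluated first), convergent
(tail-to-tail: the overlap includes both 3' termini) and divergent
(head-to-head).  With CDS annotations the overlap is further classed as
pure 3'-UTR (touching neither coding region and lying 3' of both) or
CDS-involved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustermerge import ESTGene, ESTTranscript

__all__ = [
    "SCP",
    "find_scps",
    "classify_orientation",
    "classify_coding",
    "scp_summary",
]


@dataclass
class SCP:
    gene_a: str  # + strand member
    gene_b: str  # - strand member
    contig: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    overlap: tuple[int, int]
    orientation: str = ""
    coding_class: str = "undetermined"


def _junction_confirmed(gene: ESTGene,
                        transcripts: dict[str, ESTTranscript],
                        contigs: dict[str, str]) -> bool:
    """At least one GT-AG intron (read in the gene's orientation)."""
    genome = contigs[gene.contig]
    for tid in gene.member_transcript_ids:
        for s, e in transcripts[tid].introns:
            d, a = genome[s:s + 2], genome[e - 2:e]
            if gene.strand == "+" and (d, a) == ("GT", "AG"):
                return True
            if gene.strand == "-" and (d, a) == ("CT", "AC"):
                return True
    return False


def find_scps(estgenes: list[ESTGene],
              transcripts: dict[str, ESTTranscript],
              contigs: dict[str, str]) -> list[SCP]:
    """All (+,-) gene pairs with overlapping spans, both junction-confirmed.

    Unknown-strand genes are excluded.  Output order is deterministic in
    genomic coordinates, independent of input enumeration order.
    """
    plus = sorted((g for g in estgenes if g.strand == "+"),
                  key=lambda g: (g.contig, g.span, g.id))
    minus = sorted((g for g in estgenes if g.strand == "-"),
                   key=lambda g: (g.contig, g.span, g.id))
    out = []
    for ga in plus:
        if not _junction_confirmed(ga, transcripts, contigs):
            continue
        for gb in minus:
            if gb.contig != ga.contig:
                continue
            lo = max(ga.span[0], gb.span[0])
            hi = min(ga.span[1], gb.span[1])
            if lo >= hi:
                continue
            if not _junction_confirmed(gb, transcripts, contigs):
                continue
            scp = SCP(ga.id, gb.id, ga.contig, ga.span, gb.span, (lo, hi))
            scp.orientation = classify_orientation(scp)
            out.append(scp)
    return out


def classify_orientation(scp: SCP) -> str:
    """contained > convergent (tail-to-tail) > divergent (head-to-head).

    On the forward axis the + gene's 3' terminus is its right end and the
    - gene's 3' terminus its left end, so a convergent overlap contains
    span_a's right end and span_b's left end.
    """
    (a0, a1), (b0, b1) = scp.span_a, scp.span_b
    if (a0 <= b0 and b1 <= a1) or (b0 <= a0 and a1 <= b1):
        return "contained"
    lo, hi = scp.overlap
    if lo <= b0 and hi >= a1:
        return "convergent"
    return "divergent"


def classify_coding(scp: SCP,
                    cds: dict[str, tuple[int, int]]) -> str:
    """pure_3utr iff the overlap misses both CDS and lies 3' of each CDS in
    that gene's own orientation; cds_involved otherwise; undetermined when
    either CDS is unknown."""
    ca = cds.get(scp.gene_a)
    cb = cds.get(scp.gene_b)
    if ca is None or cb is None:
        scp.coding_class = "undetermined"
        return scp.coding_class
    lo, hi = scp.overlap

    def hits(c):
        return lo < c[1] and c[0] < hi

    # 3' of the + gene = right of its CDS end; 3' of the - gene = left of
    # its CDS start
    three_prime_a = lo >= ca[1]
    three_prime_b = hi <= cb[0]
    if not hits(ca) and not hits(cb) and three_prime_a and three_prime_b:
        scp.coding_class = "pure_3utr"
    else:
        scp.coding_class = "cds_involved"
    return scp.coding_class


def scp_summary(scps: list[SCP]) -> dict:
    """Counts plus display percentages (nearest integer)."""
    n = len(scps)
    counts = {o: sum(1 for s in scps if s.orientation == o)
              for o in ("convergent", "divergent", "contained")}
    coding = {c: sum(1 for s in scps if s.coding_class == c)
              for c in ("pure_3utr", "cds_involved", "undetermined")}
    conv = [s for s in scps if s.orientation == "convergent"]
    conv_coding = [s for s in conv if s.coding_class != "undetermined"]
    conv_utr = sum(1 for s in conv_coding if s.coding_class == "pure_3utr")
    out = {
        "n": n,
        "orientation_counts": counts,
        "coding_counts": coding,
        "convergent_percent": (round(100.0 * counts["convergent"] / n)
                               if n else None),
        "n_convergent_coding": len(conv_coding),
        "convergent_coding_percent": (
            round(100.0 * len(conv_coding) / len(conv)) if conv else None),
        "pure_3utr_of_convergent_percent": (
            round(100.0 * conv_utr / len(conv_coding)) if conv_coding else None),
    }
    return out
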