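"""EST-to-genome spliced alignment.

A deliberately small anchored spliced aligner for the low-divergence,
desk-scale regime of the synthetic genome: exact k-mer anchors are grouped
into diagonal segments, segments are chained colinearly, and inter-segment
genomic gaps in the allowed intron size range become introns whose exact
boundary is placed to maximize flanking matches plus a canonical splice-site
bonus (GT..AG forward, CT..AC reverse).  Externally produced alignments can
be imported from GFF3 instead.

Alignments are always stored on forward genome coordinates; the strand of
the transcript is inferred downstream from splice-junction consensus, not
from read orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import revcomp

__all__ = [
    "AlignParams",
    "SplicedAlignment",
    "GenomeIndex",
    "IntronStats",
    "MappingReport",
    "spliced_align",
    "align_all",
    "export_alignments",
    "import_alignments",
    "filter_mapped",
    "intron_summary",
]


@dataclass
class AlignParams:
    anchor_k: int = 14
    anchor_step: int = 2
    min_intron: int = 20
    max_intron: int = 5000
    match: int = 1
    mismatch: int = -2
    gap: int = -3
    splice_bonus: int = 4
    min_chain_bases: int = 30  # weakest anchor chain worth reporting

    def __post_init__(self):
        if self.anchor_k < 8:
            raise ValueError("anchor_k must be >= 8")
        if self.min_intron >= self.max_intron:
            raise ValueError("min_intron must be < max_intron")


@dataclass
class SplicedAlignment:
    """One EST placed on one contig as ordered, gapless-or-indel blocks.

    ``blocks`` pairs a genome interval with an EST interval (both 0-based
    half-open, strictly increasing); gaps between consecutive genome blocks
    are the ``introns`` (genome interval plus donor/acceptor dinucleotides
    as read on the forward strand).  ``est_reversed`` records that the
    reverse complement of the submitted read was placed; EST offsets refer
    to the aligned orientation.
    """

    est_id: str
    contig: str
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    mismatch_positions: list[int] = field(default_factory=list)
    indel_runs: list[tuple[int, int, str]] = field(default_factory=list)
    introns: list[tuple[int, int, str, str]] = field(default_factory=list)
    identity: float = 0.0
    est_coverage: float = 0.0
    strand_call: str = "unknown"
    est_reversed: bool = False
    est_length: int = 0
    score: float = 0.0
    library: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0][0], self.blocks[-1][0][1]

    @property
    def genome_blocks(self) -> list[tuple[int, int]]:
        return [g for g, _ in self.blocks]

    @property
    def intron_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _, _ in self.introns]

    @property
    def spliced(self) -> bool:
        return len(self.introns) > 0


class GenomeIndex:
    """Exact k-mer index over all contigs."""

    def __init__(self, contigs: dict[str, str], k: int = 14):
        self.contigs = contigs
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in contigs.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((cid, i))


def _segments(read: str, gidx: GenomeIndex, params: AlignParams):
    """Diagonal anchor segments per contig: (contig, qs, qe, gs, ge)."""
    k, step = params.anchor_k, params.anchor_step
    anchors: dict[tuple[str, int], list[int]] = {}
    positions = list(range(0, max(len(read) - k + 1, 0), step))
    if positions and positions[-1] != len(read) - k:
        positions.append(len(read) - k)
    for q in positions:
        for cid, g in gidx.index.get(read[q:q + k], ()):
            anchors.setdefault((cid, g - q), []).append(q)
    segs = []
    for (cid, diag), qs_list in anchors.items():
        qs_list.sort()
        start = prev = qs_list[0]
        for q in qs_list[1:]:
            if q - prev <= step:
                prev = q
            else:
                segs.append((cid, start, prev + k, start + diag, prev + k + diag))
                start = prev = q
        segs.append((cid, start, prev + k, start + diag, prev + k + diag))
    return segs


def _chain(segs, params: AlignParams):
    """Best colinear chain per contig (weighted LIS over segments)."""
    by_contig: dict[str, list] = {}
    for s in segs:
        by_contig.setdefault(s[0], []).append(s)
    best_chain, best_score, best_key = None, -1.0, None
    for cid, ss in sorted(by_contig.items()):
        ss.sort(key=lambda s: (s[1], s[3]))
        n = len(ss)
        score = [float(s[2] - s[1]) for s in ss]
        parent = [-1] * n
        for i in range(n):
            for j in range(i):
                qgap = ss[i][1] - ss[j][2]
                ggap = ss[i][3] - ss[j][4]
                if qgap < -params.anchor_k * 2 or ggap <= qgap - 30:
                    continue
                if ggap - max(qgap, 0) > params.max_intron:
                    continue
                gain = ss[i][2] - ss[i][1] + min(qgap, 0)
                cand = score[j] + gain - (1.0 if ggap != qgap else 0.0)
                if cand > score[i]:
                    score[i], parent[i] = cand, j
        i_best = int(np.argmax(score))
        if score[i_best] > best_score + 1e-9 or (
                abs(score[i_best] - best_score) <= 1e-9 and best_key is not None
                and (ss[i_best][3], cid) < best_key):
            chain = []
            i = i_best
            while i != -1:
                chain.append(ss[i])
                i = parent[i]
            chain.reverse()
            best_chain, best_score = chain, score[i_best]
            best_key = (chain[0][3], cid)
    return best_chain, best_score


def _splice_site_bonus(genome: str, gs: int, ge: int, params: AlignParams) -> int:
    # forward-strand dinucleotides of GT:AG, GC:AG, AT:AC introns on either
    # transcript strand
    d, a = genome[gs:gs + 2], genome[ge - 2:ge]
    if (d, a) in (("GT", "AG"), ("CT", "AC"), ("GC", "AG"), ("CT", "GC"),
                  ("AT", "AC"), ("GT", "AT")):
        return params.splice_bonus
    return 0


def _close_gap(read, genome, b1, a2, d1, c2, params):
    """Place the boundary within a junction/indel gap.

    Read bases [b1, a2) are unaligned between exon blocks ending at genome
    d1 and starting at genome c2.  Returns (t, intron, n_match, mismatches)
    where t is the chosen read split point.
    """
    # Anchored segments can overrun the true junction when the sequence on
    # the far side coincides, so the split point is searched in a window
    # extending into both anchored flanks, not just the unaligned gap.
    intron_len = (c2 - d1) - (a2 - b1)
    w = 25
    lo = max(b1 - w, 1, b1 - d1)
    hi = min(a2 + w, len(read) - 1, b1 + (len(genome) - d1))
    if hi < lo:
        lo = hi = max(min(b1, hi), lo)
    best = None
    for t in range(lo, hi + 1):
        gs = d1 + (t - b1)
        ge = c2 - (a2 - t)
        if gs < 0 or ge > len(genome) or (gs >= ge and intron_len > 0):
            continue
        score = 0
        mism = []
        for q in range(lo, hi):
            g = d1 + (q - b1) if q < t else c2 - (a2 - q)
            if 0 <= g < len(genome) and read[q] == genome[g]:
                score += params.match
            else:
                score += params.mismatch
                mism.append(q)
        if intron_len >= params.min_intron:
            score += _splice_site_bonus(genome, gs, ge, params)
        if best is None or score > best[0]:
            best = (score, t, gs, ge, mism)
    if best is None:
        return b1, (d1, c2), 0, []
    _, t, gs, ge, mism = best
    return t, (gs, ge), best[0], mism


def spliced_align(est_id: str, read: str, gidx: GenomeIndex,
                  params: AlignParams | None = None) -> SplicedAlignment | None:
    """Best spliced placement of a read (either orientation) or None."""
    params = params or AlignParams()
    best = None
    for reversed_flag, seq in ((False, read), (True, revcomp(read))):
        aln = _align_oriented(est_id, seq, gidx, params, reversed_flag)
        if aln is None:
            continue
        if (best is None or aln.score > best.score + 1e-9
                or (abs(aln.score - best.score) <= 1e-9
                    and (aln.span[0], aln.contig) < (best.span[0], best.contig))):
            best = aln
    return best


_ACCEPTOR_FWD = ("AG", "AC", "GC", "AT")
_DONOR_FWD = ("GT", "CT", "GC", "AT")


def _rescue_termini(seq, genome, cleaned, params, min_fragment=8):
    """Attach terminal read fragments shorter than the anchor k-mer.

    A trailing fragment is rescued when it occurs exactly in the genome
    within intron range of the last block and the implied intron end carries
    a splice-class dinucleotide; mirrored for the leading fragment.
    """
    qe, ge = cleaned[-1][1], cleaned[-1][3]
    frag = seq[qe:]
    m = len(frag)
    if m >= min_fragment:
        win_lo = ge + params.min_intron
        win_hi = min(ge + params.max_intron, len(genome) - m)
        hits = []
        g = genome.find(frag, win_lo, win_hi + m)
        while g != -1 and len(hits) < 4:
            if genome[g - 2:g] in _ACCEPTOR_FWD:
                hits.append(g)
            g = genome.find(frag, g + 1, win_hi + m)
        if len(hits) == 1:  # ambiguous placements are left unaligned
            cleaned.append([qe, len(seq), hits[0], hits[0] + m])
    qs, gs = cleaned[0][0], cleaned[0][2]
    frag = seq[:qs]
    m = len(frag)
    if m >= min_fragment:
        win_lo = max(gs - params.max_intron - m, 0)
        win_hi = gs - params.min_intron - m
        hits = []
        g = genome.find(frag, win_lo, win_hi + m)
        while g != -1 and len(hits) < 4:
            if genome[g + m:g + m + 2] in _DONOR_FWD:
                hits.append(g)
            g = genome.find(frag, g + 1, win_hi + m)
        if len(hits) == 1:
            cleaned.insert(0, [0, qs, hits[0], hits[0] + m])


def _align_oriented(est_id, seq, gidx, params, reversed_flag):
    segs = _segments(seq, gidx, params)
    if not segs:
        return None
    chain, chain_score = _chain(segs, params)
    if chain is None or chain_score < params.min_chain_bases:
        return None
    cid = chain[0][0]
    genome = gidx.contigs[cid]

    # resolve read overlaps between consecutive segments
    cleaned = [list(chain[0][1:])]  # [qs, qe, gs, ge]
    for _, qs, qe, gs, ge in chain[1:]:
        prev = cleaned[-1]
        if qs < prev[1]:
            delta = prev[1] - qs
            qs += delta
            gs += delta
        if qe <= qs or ge <= gs:
            continue
        cleaned.append([qs, qe, gs, ge])

    # extend terminal segments outward over exact matches
    qs, qe, gs, ge = cleaned[0]
    while qs > 0 and gs > 0 and seq[qs - 1] == genome[gs - 1]:
        qs -= 1
        gs -= 1
    cleaned[0][0], cleaned[0][2] = qs, gs
    qs, qe, gs, ge = cleaned[-1]
    while qe < len(seq) and ge < len(genome) and seq[qe] == genome[ge]:
        qe += 1
        ge += 1
    cleaned[-1][1], cleaned[-1][3] = qe, ge

    # rescue unanchored terminal exon fragments (too short to seed a k-mer):
    # exact fragment occurrence across a plausible intron with a splice-class
    # dinucleotide on the intron side
    _rescue_termini(seq, genome, cleaned, params)

    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    introns: list[tuple[int, int, str, str]] = []
    mismatches: list[int] = []
    indel_runs: list[tuple[int, int, str]] = []
    cur = cleaned[0]
    for nxt in cleaned[1:]:
        b1, d1 = cur[1], cur[3]
        a2, c2 = nxt[0], nxt[2]
        ggap = c2 - d1
        qgap = a2 - b1
        if ggap - qgap >= params.min_intron:
            t, (isv, iev), _, mism = _close_gap(seq, genome, b1, a2, d1, c2, params)
            mismatches.extend(mism)
            blocks.append(((cur[2], d1 + (t - b1)), (cur[0], t)))
            introns.append((isv, iev, genome[isv:isv + 2], genome[iev - 2:iev]))
            cur = [t, nxt[1], iev, nxt[3]]
        else:
            # small gap: mismatch run and/or short indel inside one exon
            for q in range(b1, a2):
                g = d1 + (q - b1)
                if g >= c2 or g >= len(genome) or seq[q] != genome[g]:
                    mismatches.append(q)
            if ggap != qgap:
                side = "del" if ggap > qgap else "ins"
                indel_runs.append((b1, abs(ggap - qgap), side))
            cur = [cur[0], nxt[1], cur[2], nxt[3]]
    blocks.append(((cur[2], cur[3]), (cur[0], cur[1])))

    # mismatches inside matched block interiors
    for (gs_, ge_), (qs_, qe_) in blocks:
        ln = min(ge_ - gs_, qe_ - qs_)
        for off in range(ln):
            if genome[gs_ + off] != seq[qs_ + off] and (qs_ + off) not in mismatches:
                mismatches.append(qs_ + off)
    mismatches = sorted(set(mismatches))

    aligned_est = sum(q1 - q0 for _, (q0, q1) in blocks)
    columns = sum(max(g1 - g0, q1 - q0) for (g0, g1), (q0, q1) in blocks)
    n_mm = len(mismatches)
    n_indel_cols = sum(l for _, l, _ in indel_runs)
    n_matches = columns - n_mm - n_indel_cols
    identity = n_matches / columns if columns else 0.0
    coverage = aligned_est / len(seq) if seq else 0.0
    score = (params.match * n_matches + params.mismatch * n_mm
             + params.gap * len(indel_runs))
    return SplicedAlignment(
        est_id=est_id, contig=cid, blocks=blocks,
        mismatch_positions=mismatches, indel_runs=indel_runs, introns=introns,
        identity=identity, est_coverage=coverage, est_reversed=reversed_flag,
        est_length=len(seq), score=score)


def align_all(reads: dict[str, str], gidx: GenomeIndex,
              params: AlignParams | None = None,
              libraries: dict[str, str] | None = None
              ) -> tuple[list[SplicedAlignment], list[str]]:
    """Align every read; returns (alignments, unmapped read ids)."""
    params = params or AlignParams()
    alns, unmapped = [], []
    for rid, seq in reads.items():
        a = spliced_align(rid, seq, gidx, params)
        if a is None:
            unmapped.append(rid)
        else:
            if libraries:
                a.library = libraries.get(rid)
            alns.append(a)
    return alns, unmapped


# ---------------------------------------------------------------------------
# GFF3 round trip
# ---------------------------------------------------------------------------

def export_alignments(alignments: list[SplicedAlignment], path: str) -> None:
    """Write alignments as GFF3 match/match_part (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(alignments, 1):
            mid = f"match{i:06d}"
            s, e = a.span
            attrs = (f"ID={mid};Name={a.est_id};identity={a.identity:.6f};"
                     f"coverage={a.est_coverage:.6f};reversed={int(a.est_reversed)};"
                     f"est_length={a.est_length}")
            if a.library:
                attrs += f";library={a.library}"
            fh.write(f"{a.contig}\testforge\tmatch\t{s+1}\t{e}\t{a.score:.1f}"
                     f"\t.\t.\t{attrs}\n")
            for (gs, ge), (qs, qe) in a.blocks:
                fh.write(f"{a.contig}\testforge\tmatch_part\t{gs+1}\t{ge}\t.\t.\t."
                         f"\tParent={mid};Target={a.est_id} {qs+1} {qe}\n")


def import_alignments(path: str, contigs: dict[str, str]
                      ) -> list[SplicedAlignment]:
    """Read match/match_part GFF3; re-derives introns and dinucleotides
    from the genome.  Raises ValueError with the line number on bad input."""
    matches: dict[str, SplicedAlignment] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            contig, _, ftype, start, end, score, _, _, attr_s = parts
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            if ftype == "match":
                a = SplicedAlignment(
                    est_id=attrs.get("Name", attrs["ID"]), contig=contig,
                    blocks=[],
                    identity=float(attrs.get("identity", 0.0)),
                    est_coverage=float(attrs.get("coverage", 0.0)),
                    est_reversed=bool(int(attrs.get("reversed", 0))),
                    est_length=int(attrs.get("est_length", 0)),
                    score=float(score) if score not in (".", "") else 0.0,
                    library=attrs.get("library"))
                matches[attrs["ID"]] = a
                order.append(attrs["ID"])
            elif ftype == "match_part":
                pid = attrs.get("Parent")
                if pid not in matches:
                    raise ValueError(f"{path}:{lineno}: match_part before match")
                tgt = attrs.get("Target", "").split()
                if len(tgt) < 3:
                    raise ValueError(f"{path}:{lineno}: missing Target")
                qs, qe = int(tgt[1]) - 1, int(tgt[2])
                matches[pid].blocks.append(((start_i, end_i), (qs, qe)))
    out = []
    for mid in order:
        a = matches[mid]
        if not a.blocks:
            raise ValueError(f"{path}: match {mid} has no match_part rows")
        a.blocks.sort(key=lambda b: b[0])
        genome = contigs.get(a.contig, "")
        a.introns = [
            (g1, g2, genome[g1:g1 + 2], genome[g2 - 2:g2])
            for (_, g1), (g2, _) in zip(
                (b[0] for b in a.blocks), (b[0] for b in a.blocks[1:]))]
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# the study's mapping-quality filter and intron statistics
# ---------------------------------------------------------------------------

def filter_mapped(alignments: list[SplicedAlignment],
                  min_identity: float = 0.90, min_coverage: float = 0.90
                  ) -> tuple[list[SplicedAlignment], "MappingReport"]:
    """Keep alignments with identity >= 0.90 and coverage >= 0.90
    ("no less than" — boundary inclusive); per-library accounting."""
    kept = [a for a in alignments
            if a.identity >= min_identity - 1e-12
            and a.est_coverage >= min_coverage - 1e-12]
    report = MappingReport.from_alignments(alignments, kept)
    return kept, report


@dataclass
class MappingReport:
    """Per-library counts of aligned / well-mapped / spliced ESTs."""

    libraries: list[str]
    aligned: dict[str, int]
    mapped: dict[str, int]
    spliced: dict[str, int]

    @classmethod
    def from_alignments(cls, alignments, kept):
        libs = sorted({a.library or "all" for a in alignments}) or ["all"]
        aligned = {l: 0 for l in libs}
        mapped = {l: 0 for l in libs}
        spliced = {l: 0 for l in libs}
        for a in alignments:
            aligned[a.library or "all"] += 1
        for a in kept:
            lib = a.library or "all"
            mapped[lib] += 1
            if a.spliced:
                spliced[lib] += 1
        return cls(libs, aligned, mapped, spliced)

    @classmethod
    def from_counts(cls, filtered: dict[str, int], mapped: dict[str, int],
                    spliced: dict[str, int]) -> "MappingReport":
        """Build a report from externally tabulated per-library counts."""
        return cls(list(filtered), dict(filtered), dict(mapped), dict(spliced))

    @property
    def total_aligned(self) -> int:
        return sum(self.aligned.values())

    @property
    def total_mapped(self) -> int:
        return sum(self.mapped.values())

    @property
    def total_spliced(self) -> int:
        return sum(self.spliced.values())

    def mapped_percent(self) -> float:
        """Well-mapped share of aligned ESTs, displayed as percent."""
        return 100.0 * self.total_mapped / self.total_aligned

    def spliced_percent(self) -> float:
        """Spliced share of well-mapped ESTs, displayed as percent."""
        return 100.0 * self.total_spliced / self.total_mapped


@dataclass
class IntronStats:
    n: int
    median: float | None
    minimum: int | None
    fraction_below_2kb: float | None
    fraction_above_200: float | None
    defined: bool

    @classmethod
    def empty(cls):
        return cls(0, None, None, None, None, False)


def intron_summary(alignments: list[SplicedAlignment]) -> IntronStats:
    """Statistics over unique intron calls (same contig+coords counted once)."""
    uniq = {(a.contig, s, e) for a in alignments for s, e, _, _ in a.introns}
    if not uniq:
        return IntronStats.empty()
    lens = np.array(sorted(e - s for _, s, e in uniq))
    return IntronStats(
        n=len(lens), median=float(np.median(lens)), minimum=int(lens.min()),
        fraction_below_2kb=float(np.mean(lens < 2000)),
        fraction_above_200=float(np.mean(lens > 200)), defined=True)
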