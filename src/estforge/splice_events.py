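"""Alternative-splicing event detection with reliability filters.

Events are called by comparing the intron chains of the transcripts within
one ESTGene:

* CE / CSE — transcript A includes a block of consecutive internal exons
  that transcript B skips with a single intron whose donor equals the donor
  of A's upstream flanking intron and whose acceptor equals the acceptor of
  A's downstream flanking intron (CE when one exon is skipped, CSE for a
  stretch).
* RI — transcript B retains A's intron inside one exon that extends beyond
  both intron boundaries.
* ALT5 / ALT3 — two introns share exactly one splice site; which side is
  alternative is read in the gene's own orientation.

In place of manual curation, an event is "reliable" only if the supporting
alignments pass three filters: every intron canonical (configurable site
set), every indel run outside introns shorter than 9 bases, and each event
boundary flanked by at least three consecutive exactly matching aligned
bases in at least one supporting alignment per side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import SplicedAlignment
from .clustermerge import ESTGene, ESTTranscript

__all__ = [
    "SpliceEvent",
    "FilterSpec",
    "PAPER_LITERAL_SITES",
    "detect_events",
    "apply_filters",
    "count_events",
]

#: Standard canonical set: the major GT:AG plus minor GC:AG and AT:AC.
DEFAULT_SITES = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})
#: Literal variant with CG:AG in place of GC:AG, kept as a preset.
PAPER_LITERAL_SITES = frozenset({("GT", "AG"), ("CG", "AG"), ("AT", "AC")})


@dataclass
class FilterSpec:
    canonical_site_set: frozenset = DEFAULT_SITES
    max_indel_run: int = 9      # exclusive bound: runs must be < 9 bases
    min_flank_matches: int = 3
    require_all_alignments_flank: bool = False

    def __post_init__(self):
        if not self.canonical_site_set:
            raise ValueError("canonical_site_set must be non-empty")
        if self.max_indel_run < 1:
            raise ValueError("max_indel_run must be >= 1")


@dataclass
class SpliceEvent:
    event_type: str  # CE | CSE | RI | ALT5 | ALT3
    gene_id: str
    coordinates: tuple[int, int]
    exon_count: int = 1
    inclusion_transcripts: set[str] = field(default_factory=set)
    exclusion_transcripts: set[str] = field(default_factory=set)
    canonical_sites: bool = False
    indel_ok: bool = False
    flank_matches: bool = False

    @property
    def reliable(self) -> bool:
        return self.canonical_sites and self.indel_ok and self.flank_matches


def _exons_between(t: ESTTranscript, lo: int, hi: int) -> list[tuple[int, int]]:
    return [e for e in t.exons if e[0] >= lo and e[1] <= hi]


def detect_events(gene: ESTGene, transcripts: dict[str, ESTTranscript]
                  ) -> list[SpliceEvent]:
    """Compare all transcript pairs of one gene; deduplicate by type and
    coordinates."""
    members = [transcripts[tid] for tid in gene.member_transcript_ids]
    found: dict[tuple, SpliceEvent] = {}

    def record(etype, coords, n_ex, incl, excl):
        key = (etype, coords)
        ev = found.get(key)
        if ev is None:
            ev = SpliceEvent(etype, gene.id, coords, n_ex)
            found[key] = ev
        ev.inclusion_transcripts.add(incl)
        ev.exclusion_transcripts.add(excl)

    for a in members:
        a_introns = set(a.introns)
        a_donors = {s: (s, e) for s, e in a.introns}
        a_acceptors = {e: (s, e) for s, e in a.introns}
        for b in members:
            if a is b:
                continue
            for s, e in b.introns:
                if (s, e) in a_introns:
                    continue
                # CE / CSE: b's intron spans >=1 whole internal exon of a and
                # reuses a's flanking donor and acceptor
                up = a_donors.get(s)
                down = a_acceptors.get(e)
                is_skipping = False
                if up and down and up != down and up[1] < down[0]:
                    skipped = _exons_between(a, up[1], down[0])
                    if skipped and all(
                            x[0] >= s and x[1] <= e for x in skipped):
                        coords = (skipped[0][0], skipped[-1][1])
                        record("CE" if len(skipped) == 1 else "CSE",
                               coords, len(skipped), a.id, b.id)
                        is_skipping = True
                if is_skipping:
                    continue
                # ALT5 / ALT3: share exactly one boundary with an intron of a;
                # a differing region that swallows a whole exon is a skipping
                # difference, not an alternative site
                for s2, e2 in a.introns:
                    if (s2 == s) != (e2 == e):
                        start_differs = s2 != s
                        if start_differs:
                            coords = (min(s, s2), max(s, s2))
                        else:
                            coords = (min(e, e2), max(e, e2))
                        if any(x[0] >= coords[0] and x[1] <= coords[1]
                               for x in list(a.exons) + list(b.exons)):
                            continue
                        if gene.strand == "-":
                            etype = "ALT5" if not start_differs else "ALT3"
                        else:
                            etype = "ALT5" if start_differs else "ALT3"
                        pair = tuple(sorted([a.id, b.id]))
                        record(etype, coords, 1, pair[0], pair[1])
            # RI: a's intron fully inside one exon of b
            for s, e in a.introns:
                for xs, xe in b.exons:
                    if xs < s and e < xe:
                        record("RI", (s, e), 1, b.id, a.id)
    return sorted(found.values(),
                  key=lambda ev: (ev.coordinates, ev.event_type))


# ---------------------------------------------------------------------------
# reliability filters
# ---------------------------------------------------------------------------

def _oriented_dinucs(a: SplicedAlignment, strand: str):
    from .simulate import revcomp
    for s, e, d, acc in a.introns:
        if strand == "-":
            yield (revcomp(acc), revcomp(d))
        else:
            yield (d, acc)


def _est_pos(a: SplicedAlignment, gpos: int, side: str) -> int | None:
    """EST offset whose aligned genome position is adjacent to ``gpos``:
    side 'left' = last aligned base before gpos, 'right' = first at/after."""
    for (gs, ge), (qs, qe) in a.blocks:
        if side == "left" and gs < gpos <= ge:
            return qs + (gpos - gs) - 1
        if side == "right" and gs <= gpos < ge:
            return qs + (gpos - gs)
    return None


def _clean_flank(a: SplicedAlignment, gpos: int, side: str, n: int
                 ) -> bool | None:
    """n consecutive exactly matching aligned bases on `side` of gpos;
    None when the alignment has no aligned base adjacent to gpos on that
    side (e.g. the far side of a splice junction)."""
    q = _est_pos(a, gpos, side)
    if q is None:
        return None
    mism = set(a.mismatch_positions)
    indel_q = {p for p, l, _ in a.indel_runs}
    step = -1 if side == "left" else 1
    # the n bases must stay inside one block and match exactly
    for i in range(n):
        qq = q + step * i
        if qq in mism or qq in indel_q:
            return False
        inside = any(qs <= qq < qe for _, (qs, qe) in a.blocks)
        if not inside:
            return False
    return True


def apply_filters(event: SpliceEvent,
                  supporting: dict[str, list[SplicedAlignment]],
                  spec: FilterSpec | None = None,
                  strand: str = "+") -> SpliceEvent:
    """Set the three reliability flags on ``event`` in place.

    ``supporting`` maps transcript id -> its supporting alignments; only
    alignments of transcripts referenced by the event are consulted.
    """
    spec = spec or FilterSpec()
    alns = [a for tid in (event.inclusion_transcripts
                          | event.exclusion_transcripts)
            for a in supporting.get(tid, [])]
    spliced = [a for a in alns if a.spliced]

    event.canonical_sites = bool(spliced) and all(
        d in spec.canonical_site_set
        for a in spliced for d in _oriented_dinucs(a, strand))

    event.indel_ok = all(
        length < spec.max_indel_run for a in alns
        for _, length, _ in a.indel_runs)

    lo, hi = event.coordinates
    ok_sides = []
    for gpos in (lo, hi):
        checks = []
        for a in alns:
            for side in ("left", "right"):
                got = _clean_flank(a, gpos, side, spec.min_flank_matches)
                if got is not None:
                    checks.append(got)
        qualifying = [c for c in checks if c]
        if spec.require_all_alignments_flank:
            ok_sides.append(bool(checks) and all(checks))
        else:
            ok_sides.append(bool(qualifying))
    event.flank_matches = all(ok_sides)
    return event


def count_events(events: list[SpliceEvent], level: str = "gene"
                 ) -> dict[str, int]:
    """Tally reliable events.

    gene level: distinct genes with >= 1 reliable event of each type;
    exon level: affected exons (a CSE of k exons contributes k).
    """
    if level not in ("gene", "exon"):
        raise ValueError("level must be 'gene' or 'exon'")
    out: dict[str, int] = {}
    if level == "gene":
        seen: dict[str, set[str]] = {}
        for ev in events:
            if ev.reliable:
                seen.setdefault(ev.event_type, set()).add(ev.gene_id)
        out = {k: len(v) for k, v in seen.items()}
    else:
        for ev in events:
            if ev.reliable:
                out[ev.event_type] = out.get(ev.event_type, 0) + ev.exon_count
    return out
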