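"""Shared fixtures: one standard simulated study per session, plus truth
scoring helpers used by recovery tests."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from estforge import (
    GenomeIndex, SimConfig, align_all, build_counts, build_transcripts,
    filter_mapped, sample_ests, simulate_genome,
)
from estforge.simulate import revcomp
from estforge.splice_events import FilterSpec, apply_filters, detect_events

#: Fixed seed of the standard study; every recovery figure in the suite is
#: computed on this one simulation.
STUDY_SEED = 7


@dataclass
class Study:
    cfg: SimConfig
    truth: object
    reads: list
    gidx: GenomeIndex
    alignments: list
    kept: list
    mapping_report: object
    transcripts: list
    genes: list
    t_by_id: dict
    events: list = field(default_factory=list)
    id2read: dict = field(default_factory=dict)

    def aln_by_est(self):
        out = defaultdict(list)
        for a in self.kept:
            out[a.est_id].append(a)
        return out


@pytest.fixture(scope="session")
def study() -> Study:
    """Noise-free standard study: default generator conditions, errors off."""
    cfg = SimConfig(seed=STUDY_SEED)
    truth = simulate_genome(cfg)
    reads = sample_ests(truth, cfg)
    gidx = GenomeIndex(truth.contigs)
    alns, _ = align_all({r.id: r.sequence for r in reads}, gidx,
                        libraries={r.id: r.library for r in reads})
    kept, report = filter_mapped(alns)
    transcripts, genes = build_transcripts(kept, truth.contigs)
    t_by_id = {t.id: t for t in transcripts}
    st = Study(cfg, truth, reads, gidx, alns, kept, report,
               transcripts, genes, t_by_id,
               id2read={r.id: r for r in reads})
    aln_by_est = st.aln_by_est()
    for g in genes:
        evs = detect_events(g, t_by_id)
        support = {tid: [a for est in t_by_id[tid].supporting_est_ids
                         for a in aln_by_est[est]]
                   for tid in g.member_transcript_ids}
        for ev in evs:
            apply_filters(ev, support, FilterSpec(), strand=g.strand)
        st.events.extend(evs)
    return st


@pytest.fixture(scope="session")
def count_matrix(study):
    """Gene x library EST counts of the standard study, with metadata."""
    lib_of = {r.id: r.library for r in study.reads}
    assignments = {}
    for g in study.genes:
        for tid in g.member_transcript_ids:
            for est in study.t_by_id[tid].supporting_est_ids:
                assignments[est] = (g.id, lib_of[est])
    libs = [l.name for l in study.cfg.libraries]
    meta = pd.DataFrame(
        {"day": [l.day for l in study.cfg.libraries],
         "karyotype": [l.karyotype for l in study.cfg.libraries]}, index=libs)
    return build_counts(assignments, libs, meta)


@pytest.fixture(scope="session")
def estgene_to_truth_gene(study):
    """Majority-vote map from reconstructed ESTGene to simulated gene."""
    out = {}
    for g in study.genes:
        c = Counter(study.id2read[e].truth.gene
                    for tid in g.member_transcript_ids
                    for e in study.t_by_id[tid].supporting_est_ids)
        out[g.id] = c.most_common(1)[0][0]
    return out


@pytest.fixture(scope="session")
def noisy_study():
    """Smaller study with realistic artifacts switched on: substitution and
    indel errors, end-degraded qualities, vector remnants, contamination."""
    from estforge.simulate import default_libraries
    cfg = SimConfig(
        seed=STUDY_SEED + 1, n_genes=40, n_contigs=2, contig_length=90000,
        sub_rate=0.005, ins_rate=2e-4, del_rate=2e-4,
        p_vector5=0.15, p_vector3=0.05, contamination_fraction=0.02,
        libraries=default_libraries(0.03))
    truth = simulate_genome(cfg)
    reads = sample_ests(truth, cfg)
    return cfg, truth, reads


@pytest.fixture(scope="session")
def noisy_cleaned(noisy_study):
    """The noisy study run through the cleaning pipeline once."""
    from estforge.preprocess import ScreenSpec, TrimSpec, run_preprocess
    from estforge.simulate import DEFAULT_CONTAMINANTS, DEFAULT_VECTOR
    _, _, reads = noisy_study
    seqs = {r.id: r.sequence for r in reads}
    quals = {r.id: r.qualities for r in reads}
    trim = TrimSpec(vector_seqs=(DEFAULT_VECTOR,))
    screen = ScreenSpec(contaminant_seqs=dict(DEFAULT_CONTAMINANTS))
    clean, report = run_preprocess(seqs, quals, trim, screen)
    return reads, quals, clean, report, trim, screen


# ---------------------------------------------------------------------------
# truth scoring helpers
# ---------------------------------------------------------------------------

def truth_intron_chain(truth, gene_id, isoform):
    return tuple(truth.genes[gene_id].introns(isoform))


def covered_junctions(study):
    """(gene, isoform) -> introns present in the kept alignments of the
    isoform's reads (the evidence that actually entered merging)."""
    iso_of = {r.id: (r.truth.gene, r.truth.isoform) for r in study.reads
              if not r.truth.contaminant}
    cov = defaultdict(set)
    for a in study.kept:
        if a.est_id in iso_of:
            cov[iso_of[a.est_id]].update((s, e) for s, e, _, _ in a.introns)
    return cov


def covered_blocks(study):
    """(gene, isoform) -> aligned genomic blocks of the isoform's reads."""
    iso_of = {r.id: (r.truth.gene, r.truth.isoform) for r in study.reads
              if not r.truth.contaminant}
    cov = defaultdict(list)
    for a in study.kept:
        if a.est_id in iso_of:
            cov[iso_of[a.est_id]].extend(a.genome_blocks)
    return cov


def gene_strand_assignable(truth, gene_id) -> bool:
    """True when every intron of every isoform is GT-AG in the gene's own
    orientation, so junction-consensus strand inference can succeed."""
    g = truth.genes[gene_id]
    seq = truth.contigs[g.contig]
    for iso in g.isoforms:
        for s, e in g.introns(iso):
            d, a = seq[s:s + 2], seq[e - 2:e]
            if g.strand == "-":
                d, a = revcomp(a), revcomp(d)
            if (d, a) != ("GT", "AG"):
                return False
    return True


def observable_planted_events(study):
    """Planted events whose evidence was actually sequenced and mappable.

    An event can only be called when (i) the gene's junctions are
    GT-AG-only so its transcripts are strand-assignable and groupable, and
    (ii) the kept reads cover the distinguishing junctions of both isoforms
    (for RI, additionally a retaining read must span the whole intron).
    3'-biased sampling leaves 5'-distal events of long genes unsequenced.
    """
    cov = covered_junctions(study)
    blocks = covered_blocks(study)
    truth = study.truth
    out = []
    for ev in truth.event_registry:
        g = truth.genes[ev.gene_id]
        if not gene_strand_assignable(truth, ev.gene_id):
            continue
        i1 = set(g.introns("iso1"))
        i2 = set(g.introns("iso2"))
        c1 = cov[(ev.gene_id, "iso1")]
        c2 = cov[(ev.gene_id, "iso2")]
        x0, x1 = ev.coordinates
        if ev.event_type in ("CE", "CSE"):
            up = next((i for i in i1 if i[1] == x0), None)
            down = next((i for i in i1 if i[0] == x1), None)
            if up is None or down is None:
                continue
            merged = (up[0], down[1])
            if up in c1 and down in c1 and merged in c2:
                out.append(ev)
        elif ev.event_type == "RI":
            spanned = any(a < x0 and x1 < b
                          for a, b in blocks[(ev.gene_id, "iso2")])
            if (x0, x1) in c1 and spanned:
                out.append(ev)
        else:  # ALT5 / ALT3
            var1 = i1 - i2
            var2 = i2 - i1
            if len(var1) == 1 and len(var2) == 1:
                if var1.pop() in c1 and var2.pop() in c2:
                    out.append(ev)
    return out


def observable_planted_isoforms(study):
    """(gene, isoform) pairs that are junction-distinguishable within their
    gene and reconstructable from the kept reads of that isoform.

    Reconstructable means what the merge rule itself requires: some set of
    the isoform's own reads, chained by shared introns (merging joins two
    alignments only when they share a splice junction), jointly covers the
    whole intron chain.  Junction evidence is taken from the kept
    alignments (what actually entered merging), labelled by truth isoform.
    """
    iso_of = {r.id: (r.truth.gene, r.truth.isoform) for r in study.reads
              if not r.truth.contaminant}
    read_introns = defaultdict(list)
    for a in study.kept:
        if a.est_id not in iso_of:
            continue
        ji = frozenset((s, e) for s, e, _, _ in a.introns)
        if ji:
            read_introns[iso_of[a.est_id]].append(ji)
    truth = study.truth
    out = []
    for gid, g in truth.genes.items():
        for iso in g.isoforms:
            chain = tuple(g.introns(iso))
            if not chain:
                continue
            others = [tuple(g.introns(i)) for i in g.isoforms if i != iso]
            if chain in others:
                continue
            # union-find over this isoform's reads, linked by shared introns
            sets = [set(ji) for ji in read_introns[(gid, iso)]]
            merged = True
            while merged:
                merged = False
                for i in range(len(sets)):
                    for j in range(i + 1, len(sets)):
                        if sets[i] & sets[j]:
                            sets[i] |= sets[j]
                            del sets[j]
                            merged = True
                            break
                    if merged:
                        break
            if any(s >= set(chain) for s in sets):
                out.append((gid, iso))
    return out
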