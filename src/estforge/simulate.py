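"""Synthetic EST study generator.

Builds a toy multi-contig genome carrying gene models with planted
alternative-splicing events (cassette exons, consecutively skipped exon
stretches, retained introns, alternative donor/acceptor sites) and planted
sense/antisense gene pairs, then samples per-library EST reads that mimic
non-normalized, oligo(dT)-primed Sanger libraries: 3'-biased fragments with
polyA/T tails, vector/adaptor remnants, end-degraded base qualities and a
small contaminant fraction.  Every read and every planted structure is
recorded in machine-readable truth tables so downstream stages (cleaning,
spliced alignment, cluster-and-merge, event detection, antisense pairing,
count tests) can be scored exactly.

Coordinates are 0-based half-open everywhere in memory; GFF3 output is
1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_VECTOR",
    "DEFAULT_CONTAMINANTS",
    "LibrarySpec",
    "SimConfig",
    "GeneModel",
    "PlantedEvent",
    "PlantedPair",
    "ReadTruth",
    "ESTRecord",
    "GenomeTruth",
    "SimSizingError",
    "default_libraries",
    "simulate_genome",
    "sample_ests",
    "write_outputs",
    "load_genome_fasta",
    "load_reads",
    "revcomp",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# Fixed cloning-artifact and contaminant sequences.  Generated once from a
# frozen local generator so the defaults are stable constants; the vector
# carries XhoI (CTCGAG) and EcoRI (GAATTC) sites like the phagemid vectors
# used for directional cDNA cloning.
_const_rng = np.random.default_rng(20130415)
DEFAULT_VECTOR = (
    _random_seq(_const_rng, 50)
    + "CTCGAG"
    + _random_seq(_const_rng, 20)
    + "GAATTC"
    + _random_seq(_const_rng, 48)
)
DEFAULT_CONTAMINANTS = {
    "ecoli_frag": _random_seq(_const_rng, 800),
    "rrna_frag": _random_seq(_const_rng, 800),
}
del _const_rng


class SimSizingError(ValueError):
    """Raised when the requested genes cannot be placed on the contigs."""


@dataclass
class LibrarySpec:
    """One cDNA library: culture day, karyotype and sequencing depth."""

    name: str
    day: int
    karyotype: str  # "monokaryon" | "dikaryon"
    target_est_count: int
    expression_profile: np.ndarray | None = None  # per-gene weights; derived if None

    def __post_init__(self):
        if self.karyotype not in ("monokaryon", "dikaryon"):
            raise ValueError(f"bad karyotype {self.karyotype!r}")
        if self.target_est_count < 0:
            raise ValueError("target_est_count must be >= 0")


def default_libraries(scale: float = 0.1) -> list[LibrarySpec]:
    """Five mycelium libraries with depths proportional to the study design.

    The full-size depths are 1,001 : 6,848 : 21,547 : 11,059 : 6,830
    (5/14/18/30-day dikaryon plus an 18-day monokaryon); ``scale`` shrinks
    them to desk scale while keeping the proportions.
    """
    raw = [
        ("5D_dik", 5, "dikaryon", 1001),
        ("14D_dik", 14, "dikaryon", 6848),
        ("18D_dik", 18, "dikaryon", 21547),
        ("18D_mono", 18, "monokaryon", 11059),
        ("30D_dik", 30, "dikaryon", 6830),
    ]
    return [
        LibrarySpec(n, d, k, int(round(c * scale))) for n, d, k, c in raw
    ]


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the standard conditions."""

    seed: int = 0
    n_contigs: int = 5
    contig_length: int = 80000
    n_genes: int = 100

    # structural distributions (log-normal parameters, hard bounds)
    exon_length_mu: float = float(np.log(170.0))
    exon_length_sigma: float = 0.45
    exon_length_min: int = 40
    exon_length_max: int = 800
    single_exon_length_mu: float = float(np.log(900.0))
    single_exon_length_sigma: float = 0.3
    intron_length_mu: float = float(np.log(280.0))  # median ~280 bases
    intron_length_sigma: float = 0.55
    intron_length_min: int = 24
    intron_length_max: int = 2000
    single_exon_gene_fraction: float = 0.15
    mean_extra_exons: float = 5.0  # n_exons = 2 + Poisson(mean) for multi-exon genes

    # splice sites
    minor_splice_site_fraction: float = 0.02
    minor_splice_sites: tuple[tuple[str, str], ...] = (("GC", "AG"), ("AT", "AC"))

    # isoform events (at most one planted event per gene)
    p_ce: float = 0.10
    p_cse: float = 0.06
    cse_len_mean: float = 2.5  # stretch length = 2 + Poisson(mean-2), capped
    p_ri: float = 0.16
    p_alt5: float = 0.04
    p_alt3: float = 0.04
    minor_isoform_fraction: float = 0.40

    # antisense pairs
    antisense_pair_rate: float = 0.08  # fraction of genes used as pair anchors
    orientation_mix: tuple[float, float, float] = (0.67, 0.07, 0.26)  # conv/div/cont
    p_utr_only: float = 0.7  # among convergent pairs, overlap restricted to 3'UTRs

    # libraries & expression
    libraries: list[LibrarySpec] = field(default_factory=default_libraries)
    expression_sigma: float = 1.0
    n_stage_overrep: int = 4
    stage_overrep_library: str = "18D_dik"
    n_strain_overrep: int = 3
    strain_overrep_library: str = "18D_mono"
    overrep_fold: float = 8.0

    # reads
    read_length_quantiles: tuple[tuple[float, int], ...] = (
        (0.0, 50), (0.25, 593), (0.5, 729), (0.75, 793), (1.0, 949),
    )
    three_prime_decay_mean: float = 150.0  # extra 5' reach beyond read, geometric
    reverse_read_fraction: float = 0.5

    # noise
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    end_ramp_amp: float = 20.0   # end quality degradation, x-fold over sub_rate
    end_ramp_tau5: float = 12.0
    end_ramp_tau3: float = 40.0

    # artifacts
    polya_min: int = 8
    polya_mean: float = 20.0
    p_vector5: float = 0.0
    p_vector3: float = 0.0
    vector_seq: str = DEFAULT_VECTOR
    adaptor_seqs: tuple[str, ...] = ()
    contamination_fraction: float = 0.0
    contaminant_seqs: dict = field(default_factory=lambda: dict(DEFAULT_CONTAMINANTS))

    def validate(self) -> None:
        probs = [
            self.minor_splice_site_fraction, self.p_ce, self.p_cse, self.p_ri,
            self.p_alt5, self.p_alt3, self.minor_isoform_fraction,
            self.antisense_pair_rate, self.p_utr_only, self.reverse_read_fraction,
            self.sub_rate, self.ins_rate, self.del_rate,
            self.p_vector5, self.p_vector3, self.contamination_fraction,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.intron_length_min < 24:
            raise ValueError("intron_length_min must be >= 24")
        if self.intron_length_max <= self.intron_length_min:
            raise ValueError("intron_length_max must exceed intron_length_min")
        if self.p_ce + self.p_cse + self.p_ri + self.p_alt5 + self.p_alt3 > 1.0:
            raise ValueError("event probabilities must sum to <= 1")


# ---------------------------------------------------------------------------
# gene and truth containers
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    id: str
    contig: str
    strand: str  # '+' or '-'
    isoforms: dict[str, list[tuple[int, int]]]  # isoform id -> ordered exons
    cds: tuple[int, int]  # genomic span of the coding region
    canonical_only: bool = False

    @property
    def span(self) -> tuple[int, int]:
        exons = [e for iso in self.isoforms.values() for e in iso]
        return min(s for s, _ in exons), max(e for _, e in exons)

    def introns(self, isoform: str) -> list[tuple[int, int]]:
        ex = self.isoforms[isoform]
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class PlantedEvent:
    gene_id: str
    event_type: str  # CE | CSE | RI | ALT5 | ALT3
    coordinates: tuple[int, int]  # genomic interval of the affected exon(s)/intron
    exon_count: int
    inclusion_isoform: str
    exclusion_isoform: str


@dataclass
class PlantedPair:
    gene_a: str  # the + strand member
    gene_b: str  # the - strand member
    orientation: str  # convergent | divergent | contained
    utr_only: bool


@dataclass
class ReadTruth:
    gene: str | None
    isoform: str | None
    blocks: list[tuple[int, int]]  # genomic intervals covered by the read core
    tail_len: int
    vector5: int  # number of vector bases at the (pre-flip) 5' end
    vector3: int
    insert_interval: tuple[int, int]  # genomic-derived core within the final read
    contaminant: bool
    reversed: bool


@dataclass
class ESTRecord:
    id: str
    library: str
    sequence: str
    qualities: np.ndarray  # per-base error probabilities
    truth: ReadTruth


@dataclass
class GenomeTruth:
    contigs: dict[str, str]
    genes: dict[str, GeneModel]
    event_registry: list[PlantedEvent]
    antisense_registry: list[PlantedPair]
    overrep_stage_genes: list[str] = field(default_factory=list)
    overrep_strain_genes: list[str] = field(default_factory=list)

    def spliced_sequence(self, gene_id: str, isoform: str) -> str:
        g = self.genes[gene_id]
        s = "".join(self.contigs[g.contig][a:b] for a, b in g.isoforms[isoform])
        return s if g.strand == "+" else revcomp(s)

    def transcript_to_genome(
        self, gene_id: str, isoform: str, t_start: int, t_end: int
    ) -> list[tuple[int, int]]:
        """Map a transcript (5'->3') interval to ordered genomic blocks."""
        g = self.genes[gene_id]
        exons = g.isoforms[isoform]
        total = sum(b - a for a, b in exons)
        t_start = max(0, min(t_start, total))
        t_end = max(t_start, min(t_end, total))
        if g.strand == "-":
            t_start, t_end = total - t_end, total - t_start
        blocks, off = [], 0
        for a, b in exons:
            ln = b - a
            lo, hi = max(t_start - off, 0), min(t_end - off, ln)
            if hi > lo:
                blocks.append((a + lo, a + hi))
            off += ln
        return blocks


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _sample_lognormal_int(rng, mu, sigma, lo, hi, n=1):
    out = []
    while len(out) < n:
        draw = rng.lognormal(mu, sigma, n - len(out))
        out.extend(int(x) for x in np.rint(draw) if lo <= x <= hi)
    return out if n > 1 else out[0]


def _pick_sites(rng, cfg: SimConfig, canonical_only: bool) -> tuple[str, str]:
    if not canonical_only and rng.random() < cfg.minor_splice_site_fraction:
        return cfg.minor_splice_sites[rng.integers(len(cfg.minor_splice_sites))]
    return ("GT", "AG")


def _build_gene_layout(rng, cfg, n_exons, canonical_only, big_exon_min=None):
    """Exon/intron lengths plus per-intron splice-site pairs, local coords."""
    ex_lens = _sample_lognormal_int(
        rng, cfg.exon_length_mu, cfg.exon_length_sigma,
        cfg.exon_length_min, cfg.exon_length_max, max(n_exons, 2))[:n_exons]
    if big_exon_min and n_exons >= 3:
        k = int(rng.integers(1, n_exons - 1))
        ex_lens[k] = max(ex_lens[k], big_exon_min)
    if n_exons > 1:
        in_lens = _sample_lognormal_int(
            rng, cfg.intron_length_mu, cfg.intron_length_sigma,
            cfg.intron_length_min, cfg.intron_length_max, max(n_exons - 1, 2))
        in_lens = in_lens[: n_exons - 1]
    else:
        in_lens = []
    sites = [_pick_sites(rng, cfg, canonical_only) for _ in in_lens]
    return ex_lens, in_lens, sites


def _exon_coords(start, ex_lens, in_lens):
    exons, pos = [], start
    for i, L in enumerate(ex_lens):
        exons.append((pos, pos + L))
        pos += L
        if i < len(in_lens):
            pos += in_lens[i]
    return exons


def _plant_event(rng, cfg, gene: GeneModel, registry: list[PlantedEvent]) -> None:
    """Attach at most one alternative isoform realising one splice event."""
    base = gene.isoforms["iso1"]
    n_exons = len(base)
    introns = gene.introns("iso1")
    kinds, weights = [], []
    for k, w in (("CE", cfg.p_ce), ("CSE", cfg.p_cse), ("RI", cfg.p_ri),
                 ("ALT5", cfg.p_alt5), ("ALT3", cfg.p_alt3)):
        kinds.append(k)
        weights.append(w)
    weights.append(1.0 - sum(weights))
    kinds.append(None)
    kind = rng.choice(kinds, p=np.array(weights) / sum(weights))
    if kind is None:
        return
    if kind in ("CE", "CSE") and n_exons < 3:
        return
    # RI needs >= 3 exons so the retaining isoform keeps a junction and
    # stays strand-assignable
    if kind == "RI" and n_exons < 3:
        return
    if kind in ("ALT5", "ALT3") and n_exons < 2:
        return

    if kind in ("CE", "CSE"):
        n_internal = n_exons - 2
        if kind == "CSE":
            if n_internal < 2:
                return
            k = min(2 + rng.poisson(max(cfg.cse_len_mean - 2.0, 0.0)), n_internal)
        else:
            k = 1
        first = int(rng.integers(1, n_exons - k))  # first skipped exon index
        alt = base[:first] + base[first + k:]
        gene.isoforms["iso2"] = alt
        coords = (base[first][0], base[first + k - 1][1])
        registry.append(PlantedEvent(gene.id, "CE" if k == 1 else "CSE",
                                     coords, k, "iso1", "iso2"))
        # the merged exclusion intron joins the upstream donor with the
        # downstream acceptor, so both flanking introns must be GT-AG
        gene._force_canonical = [introns[first - 1], introns[first + k - 1]]
    elif kind == "RI":
        j = int(rng.integers(0, n_exons - 1))
        alt = base[:j] + [(base[j][0], base[j + 1][1])] + base[j + 2:]
        gene.isoforms["iso2"] = alt
        registry.append(PlantedEvent(gene.id, "RI", introns[j], 1, "iso2", "iso1"))
    else:
        # shift one splice site inward into the intron so no new dinucleotide
        # needs planting over exon sequence shared with the base isoform
        j = int(rng.integers(0, n_exons - 1))
        s, e = introns[j]
        delta = int(rng.integers(9, 31))
        if e - s - delta < cfg.intron_length_min + 4:
            return
        # boundary moved: left boundary for ALT-at-start, right for ALT-at-end
        move_start = bool(rng.integers(2))
        alt = list(base)
        if move_start:
            alt[j] = (base[j][0], base[j][1] + delta)  # exon grows into intron
            new_intron = (s + delta, e)
            region = (s, s + delta)  # between the two variant donors
        else:
            alt[j + 1] = (base[j + 1][0] - delta, base[j + 1][1])
            new_intron = (s, e - delta)
            region = (e - delta, e)
        gene.isoforms["iso2"] = alt
        # ALT5 = alternative donor, ALT3 = alternative acceptor (biological)
        if gene.strand == "+":
            etype = "ALT5" if move_start else "ALT3"
        else:
            etype = "ALT3" if move_start else "ALT5"
        registry.append(PlantedEvent(gene.id, etype, region, 1, "iso1", "iso2"))
        gene._alt_intron = new_intron  # dinucleotides planted later
        gene._force_canonical = [introns[j]]  # alt site pairs with base site


def _write_intron_sites(seq: list[str], gene: GeneModel,
                        intron: tuple[int, int], donor: str, acceptor: str):
    s, e = intron
    if gene.strand == "+":
        seq[s:s + 2] = list(donor)
        seq[e - 2:e] = list(acceptor)
    else:
        seq[s:s + 2] = list(revcomp(acceptor))
        seq[e - 2:e] = list(revcomp(donor))


def simulate_genome(config: SimConfig) -> GenomeTruth:
    """Generate contigs, gene models, planted events and antisense pairs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig_ids = [f"contig{i+1}" for i in range(config.n_contigs)]
    seqs = {c: list(_random_seq(rng, config.contig_length)) for c in contig_ids}

    genes: dict[str, GeneModel] = {}
    events: list[PlantedEvent] = []
    pairs: list[PlantedPair] = []
    intron_sites: list[tuple[str, GeneModel, tuple[int, int], str, str]] = []

    n_pairs = int(round(config.n_genes * config.antisense_pair_rate / 2))
    n_single = config.n_genes - 2 * n_pairs
    plan: list[tuple] = []
    orient_names = ("convergent", "divergent", "contained")
    for _ in range(n_pairs):
        o = orient_names[rng.choice(3, p=np.array(config.orientation_mix) /
                                    sum(config.orientation_mix))]
        utr = o == "convergent" and rng.random() < config.p_utr_only
        plan.append(("pair", o, utr))
    plan.extend([("single",)] * n_single)
    rng.shuffle(plan)

    ci, cursor = 0, 50
    serial = [0]

    def next_id():
        serial[0] += 1
        return f"G{serial[0]:04d}"

    def place(length_needed):
        nonlocal ci, cursor
        while ci < len(contig_ids):
            if cursor + length_needed + 50 <= config.contig_length:
                start = cursor
                gap = int(rng.integers(100, 400))
                cursor = start + length_needed + gap
                return contig_ids[ci], start
            ci += 1
            cursor = 50
        raise SimSizingError(
            f"cannot place {config.n_genes} genes on {config.n_contigs} "
            f"contigs of {config.contig_length} bases; increase contig_length "
            f"or n_contigs, or lower n_genes")

    def finalize_gene(gid, contig, strand, exons, sites, canonical_only,
                      utr3_min=0):
        in_list = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        gene = GeneModel(gid, contig, strand, {"iso1": list(exons)}, (0, 0),
                         canonical_only=canonical_only)
        for intr, (d, a) in zip(in_list, sites):
            intron_sites.append((contig, gene, intr, d, a))
        # CDS inside the span, leaving UTR head-room on both terminal exons
        gs, ge = exons[0][0], exons[-1][1]
        first_len, last_len = exons[0][1] - exons[0][0], exons[-1][1] - exons[-1][0]
        if strand == "+":
            d5 = int(rng.integers(15, max(16, min(80, first_len - 10))))
            d3 = max(utr3_min, int(rng.integers(40, max(41, min(200, last_len - 10)))))
            d3 = min(d3, last_len - 5)
            gene.cds = (gs + d5, ge - d3)
        else:
            d5 = int(rng.integers(15, max(16, min(80, last_len - 10))))
            d3 = max(utr3_min, int(rng.integers(40, max(41, min(200, first_len - 10)))))
            d3 = min(d3, first_len - 5)
            gene.cds = (gs + d3, ge - d5)
        genes[gene.id] = gene
        return gene

    for item in plan:
        if item[0] == "single":
            single = rng.random() < config.single_exon_gene_fraction
            n_exons = 1 if single else 2 + int(rng.poisson(config.mean_extra_exons))
            if single:
                L = _sample_lognormal_int(
                    rng, config.single_exon_length_mu,
                    config.single_exon_length_sigma, 400, 2500)
                ex_lens, in_lens, sites = [L], [], []
            else:
                ex_lens, in_lens, sites = _build_gene_layout(
                    rng, config, n_exons, False)
            length = sum(ex_lens) + sum(in_lens)
            contig, start = place(length)
            exons = _exon_coords(start, ex_lens, in_lens)
            strand = "+" if rng.random() < 0.5 else "-"
            gene = finalize_gene(next_id(), contig, strand, exons, sites, False)
            _plant_event(rng, config, gene, events)
            # later entries overwrite earlier ones at the same position, so
            # event-flanking introns are forced back to canonical GT-AG
            for intr in getattr(gene, "_force_canonical", []):
                intron_sites.append((contig, gene, intr, "GT", "AG"))
            alt = getattr(gene, "_alt_intron", None)
            if alt is not None:
                intron_sites.append((contig, gene, alt, "GT", "AG"))
        else:
            _, orient, utr_only = item
            # pair genes: multi-exon, canonical splice sites only, big
            # terminal exons so the overlap region stays intron-free
            na = 3 + int(rng.poisson(1.5))
            nb = 2 + int(rng.poisson(1.0))
            ov = int(rng.integers(40, 150))
            if orient == "contained":
                exb, inb, sb = _build_gene_layout(rng, config, nb, True)
                lb = sum(exb) + sum(inb)
                exa, ina, sa = _build_gene_layout(rng, config, na, True,
                                                  big_exon_min=lb + 60)
                la = sum(exa) + sum(ina)
                contig, start = place(la)
                exons_a = _exon_coords(start, exa, ina)
                gene_a = finalize_gene(next_id(), contig, "+", exons_a, sa, True)
                host = max(exons_a[1:-1], key=lambda e: e[1] - e[0])
                b_start = host[0] + 20
                exons_b = _exon_coords(b_start, exb, inb)
                gene_b = finalize_gene(next_id(), contig, "-", exons_b, sb, True)
            else:
                # keep terminal exons that carry the overlap long enough
                exa, ina, sa = _build_gene_layout(rng, config, na, True)
                exb, inb, sb = _build_gene_layout(rng, config, nb, True)
                if orient == "convergent":
                    exa[-1] = max(exa[-1], ov + 120)
                    exb[0] = max(exb[0], ov + 120)
                else:
                    exa[0] = max(exa[0], ov + 60)
                    exb[-1] = max(exb[-1], ov + 60)
                la = sum(exa) + sum(ina)
                lb = sum(exb) + sum(inb)
                contig, start = place(la + lb - ov)
                if orient == "convergent":
                    exons_a = _exon_coords(start, exa, ina)
                    b_start = start + la - ov
                    exons_b = _exon_coords(b_start, exb, inb)
                    utr3_a = ov + 10 if utr_only else 0
                    gene_a = finalize_gene(next_id(), contig, "+", exons_a, sa,
                                           True, utr3_min=utr3_a)
                    gene_b = finalize_gene(next_id(), contig, "-", exons_b, sb,
                                           True, utr3_min=ov + 10 if utr_only else 0)
                else:  # divergent: B upstream on -, A downstream on +
                    exons_b = _exon_coords(start, exb, inb)
                    a_start = start + lb - ov
                    exons_a = _exon_coords(a_start, exa, ina)
                    gene_b = finalize_gene(next_id(), contig, "-", exons_b, sb, True)
                    gene_a = finalize_gene(next_id(), contig, "+", exons_a, sa, True)
            pairs.append(PlantedPair(gene_a.id, gene_b.id, orient, utr_only))

    # write splice-site dinucleotides into the sequence
    for contig, gene, intron, d, a in intron_sites:
        _write_intron_sites(seqs[contig], gene, intron, d, a)

    truth = GenomeTruth(
        contigs={c: "".join(s) for c, s in seqs.items()},
        genes=genes, event_registry=events, antisense_registry=pairs)

    # choose planted over-represented genes among multi-exon non-pair genes
    pair_ids = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    candidates = [g for g in genes if g not in pair_ids]
    rng.shuffle(candidates)
    truth.overrep_stage_genes = candidates[: config.n_stage_overrep]
    truth.overrep_strain_genes = candidates[
        config.n_stage_overrep: config.n_stage_overrep + config.n_strain_overrep]
    return truth


def _introns_of(gene, isoform):
    ex = gene.isoforms[isoform]
    return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


# ---------------------------------------------------------------------------
# expression model and read sampling
# ---------------------------------------------------------------------------

def expression_weights(truth: GenomeTruth, config: SimConfig,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-library gene abundance weights.

    Libraries share one log-normal abundance profile (a non-normalized
    library preserves it), except for planted genes that get a
    library-specific fold change: stage-specific genes are boosted in one
    culture-stage library, strain-specific genes in the monokaryon library.
    Planted genes start from an elevated baseline so they accumulate enough
    ESTs to be testable.
    """
    gene_ids = list(truth.genes)
    base = rng.lognormal(0.0, config.expression_sigma, len(gene_ids))
    boosted = set(truth.overrep_stage_genes) | set(truth.overrep_strain_genes)
    for i, g in enumerate(gene_ids):
        if g in boosted:
            base[i] = max(base[i], 3.0)
    out = {}
    for lib in config.libraries:
        if lib.expression_profile is not None:
            out[lib.name] = np.asarray(lib.expression_profile, float)
            continue
        w = base.copy()
        for i, g in enumerate(gene_ids):
            if (g in truth.overrep_stage_genes
                    and lib.name == config.stage_overrep_library):
                w[i] *= config.overrep_fold
            if (g in truth.overrep_strain_genes
                    and lib.name == config.strain_overrep_library):
                w[i] *= config.overrep_fold
        out[lib.name] = w
    return out


def _read_length(rng, config) -> int:
    qs = np.array([q for q, _ in config.read_length_quantiles])
    vs = np.array([v for _, v in config.read_length_quantiles], float)
    return int(round(float(np.interp(rng.random(), qs, vs))))


def _quality_profile(config, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    i = np.arange(n)
    ramp = (np.exp(-i / config.end_ramp_tau5)
            + np.exp(-(n - 1 - i) / config.end_ramp_tau3))
    q = config.sub_rate * (1.0 + config.end_ramp_amp * ramp)
    return np.clip(q, 0.0, 0.5)


_BASES = np.array(list("ACGT"))


def _apply_errors(rng, seq: str, qual: np.ndarray, config) -> tuple[str, np.ndarray]:
    """Substitutions at the per-base quality rate; rare indels uniformly."""
    chars = list(seq)
    if config.sub_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < qual)[0]
        for i in hits:
            alt = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alt[rng.integers(3)]
    q = list(qual)
    if config.del_rate > 0:
        for i in sorted(np.nonzero(rng.random(len(chars)) < config.del_rate)[0],
                        reverse=True):
            del chars[i], q[i]
    if config.ins_rate > 0:
        for i in sorted(np.nonzero(rng.random(len(chars) + 1) < config.ins_rate)[0],
                        reverse=True):
            chars.insert(i, _BASES[rng.integers(4)])
            q.insert(i, q[min(i, len(q) - 1)] if q else config.sub_rate)
    return "".join(chars), np.array(q)


def sample_ests(truth: GenomeTruth, config: SimConfig) -> list[ESTRecord]:
    """Draw per-library EST reads with truth records.

    Per-library read counts across genes follow a multinomial on the
    library's expression weights (non-normalized libraries: counts track
    abundance).  Fragments are 3'-biased: the insert covers the transcript
    3' end back to ``read_length + Geometric(decay)`` bases, emulating
    oligo(dT)-primed cDNA sequenced from the 5' end of the insert.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    gene_ids = list(truth.genes)
    if not gene_ids and any(l.target_est_count > 0 for l in config.libraries):
        raise ValueError("empty gene table but nonzero EST targets")
    weights = expression_weights(truth, config, rng) if gene_ids else {}
    records: list[ESTRecord] = []
    serial = 0
    cont_names = list(config.contaminant_seqs)

    for lib in config.libraries:
        n = lib.target_est_count
        if n == 0:
            continue
        w = weights[lib.name]
        if w.sum() <= 0:
            raise ValueError(f"library {lib.name} has no positive weights")
        n_cont = int(rng.binomial(n, config.contamination_fraction)) \
            if cont_names and config.contamination_fraction > 0 else 0
        counts = rng.multinomial(n - n_cont, w / w.sum())
        jobs = [g for g, c in zip(gene_ids, counts) for _ in range(c)]
        jobs += [None] * n_cont
        rng.shuffle(jobs)
        for g in jobs:
            serial += 1
            rid = f"EST{serial:06d}"
            if g is None:
                cseq = config.contaminant_seqs[cont_names[rng.integers(len(cont_names))]]
                r = min(_read_length(rng, config), len(cseq))
                st = int(rng.integers(0, len(cseq) - r + 1))
                seq = cseq[st:st + r]
                qual = _quality_profile(config, len(seq))
                seq, qual = _apply_errors(rng, seq, qual, config)
                records.append(ESTRecord(rid, lib.name, seq, qual, ReadTruth(
                    None, None, [], 0, 0, 0, (0, len(seq)), True, False)))
                continue
            gene = truth.genes[g]
            isos = list(gene.isoforms)
            if len(isos) > 1:
                iso = isos[1] if rng.random() < config.minor_isoform_fraction else isos[0]
            else:
                iso = isos[0]
            tseq = truth.spliced_sequence(g, iso)
            L = len(tseq)
            tail = int(config.polya_min + rng.poisson(config.polya_mean))
            r = _read_length(rng, config)
            extra = int(rng.geometric(1.0 / config.three_prime_decay_mean))
            lext = L + tail
            start = max(0, lext - (r + extra))
            core = (tseq + "A" * tail)[start:start + r]
            t_lo, t_hi = start, min(start + r, L)
            blocks = truth.transcript_to_genome(g, iso, t_lo, t_hi) if t_hi > t_lo else []
            tail_in_read = max(0, min(start + r, lext) - max(start, L))
            qual = _quality_profile(config, len(core))
            core, qual = _apply_errors(rng, core, qual, config)
            v5 = v3 = 0
            if config.p_vector5 > 0 and rng.random() < config.p_vector5:
                pool = (config.vector_seq,) + tuple(config.adaptor_seqs)
                vsrc = pool[rng.integers(len(pool))]
                v5 = int(rng.integers(8, min(41, len(vsrc) + 1)))
                core = vsrc[-v5:] + core
                qual = np.concatenate([_quality_profile(config, v5), qual])
            if (config.p_vector3 > 0 and start + r >= lext
                    and rng.random() < config.p_vector3):
                v3 = int(rng.integers(8, min(31, len(config.vector_seq) + 1)))
                core = core + config.vector_seq[:v3]
                qual = np.concatenate([qual, _quality_profile(config, v3)])
            rev = rng.random() < config.reverse_read_fraction
            ins_iv = (v5, len(core) - v3)
            if rev:
                core = revcomp(core)
                qual = qual[::-1].copy()
                ins_iv = (v3, len(core) - v5)
                v5, v3 = v3, v5
            records.append(ESTRecord(rid, lib.name, core, qual, ReadTruth(
                g, iso, blocks, tail_in_read, v5, v3, ins_iv, False, rev)))
    return records


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_outputs(truth: GenomeTruth, reads: list[ESTRecord], out_dir: str) -> dict:
    """Write genome FASTA, truth GFF3, reads FASTA + quality sidecar and
    tab-separated truth tables.  Returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in {
        "genome": "genome.fasta", "gff3": "truth.gff3",
        "reads": "reads.fasta", "quals": "reads.qual.tsv",
        "read_truth": "truth_reads.tsv", "events": "planted_events.tsv",
        "pairs": "antisense_pairs.tsv"}.items()}

    with open(paths["genome"], "w") as fh:
        for cid, seq in truth.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in truth.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in truth.genes.values():
            s, e = g.span
            fh.write(f"{g.contig}\testforge-sim\tgene\t{s+1}\t{e}\t.\t{g.strand}"
                     f"\t.\tID={g.id}\n")
            for iso, exons in g.isoforms.items():
                mid = f"{g.id}.{iso}"
                fh.write(f"{g.contig}\testforge-sim\tmRNA\t{exons[0][0]+1}\t"
                         f"{exons[-1][1]}\t.\t{g.strand}\t.\tID={mid};Parent={g.id}\n")
                for i, (a, b) in enumerate(exons, 1):
                    fh.write(f"{g.contig}\testforge-sim\texon\t{a+1}\t{b}\t.\t"
                             f"{g.strand}\t.\tID={mid}.e{i};Parent={mid}\n")
            ca, cb = g.cds
            fh.write(f"{g.contig}\testforge-sim\tCDS\t{ca+1}\t{cb}\t.\t{g.strand}"
                     f"\t0\tID={g.id}.cds;Parent={g.id}.iso1\n")

    with open(paths["reads"], "w") as fh:
        for r in reads:
            fh.write(f">{r.id} library={r.library}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i:i + 70] + "\n")
    with open(paths["quals"], "w") as fh:
        fh.write("read_id\terror_probs\n")
        for r in reads:
            fh.write(r.id + "\t" + ",".join(f"{q:.5g}" for q in r.qualities) + "\n")
    with open(paths["read_truth"], "w") as fh:
        fh.write("read_id\tlibrary\tgene\tisoform\tblocks\ttail_len\tvector5\t"
                 "vector3\tinsert_start\tinsert_end\tcontaminant\treversed\n")
        for r in reads:
            t = r.truth
            blocks = ";".join(f"{a}-{b}" for a, b in t.blocks)
            fh.write("\t".join(map(str, [
                r.id, r.library, t.gene or ".", t.isoform or ".", blocks or ".",
                t.tail_len, t.vector5, t.vector3, t.insert_interval[0],
                t.insert_interval[1], int(t.contaminant), int(t.reversed)])) + "\n")
    with open(paths["events"], "w") as fh:
        fh.write("gene\ttype\tstart\tend\texon_count\tinclusion\texclusion\n")
        for ev in truth.event_registry:
            fh.write("\t".join(map(str, [
                ev.gene_id, ev.event_type, ev.coordinates[0], ev.coordinates[1],
                ev.exon_count, ev.inclusion_isoform, ev.exclusion_isoform])) + "\n")
    with open(paths["pairs"], "w") as fh:
        fh.write("gene_a\tgene_b\torientation\tutr_only\n")
        for p in truth.antisense_registry:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.orientation}\t{int(p.utr_only)}\n")
    return paths


def load_genome_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_reads(fasta_path: str, qual_path: str | None = None
               ) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    from Bio import SeqIO
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(fasta_path, "fasta")}
    quals: dict[str, np.ndarray] = {}
    if qual_path:
        with open(qual_path) as fh:
            header = fh.readline()
            for line in fh:
                rid, qs = line.rstrip("\n").split("\t")
                quals[rid] = (np.array([float(x) for x in qs.split(",")])
                              if qs else np.zeros(0))
    return seqs, quals
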