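"""EST cleaning pipeline.

Raw single-pass cDNA reads carry low-quality ends, cloning vector/adaptor
remnants, polyA/T tracks and occasional foreign (contaminant) sequence.
Cleaning runs in a fixed order — quality trim, vector strip, polyA/T
removal, contamination screen, minimum-length filter — and reports exact
per-stage accounting so that input = survivors + sum of discards.

Quality trimming follows the modified-Mott rule: with per-base error
probabilities p_i and cutoff c, keep the contiguous segment maximizing
sum(c - p_i) (ties resolved leftmost).  Contamination calls use local
alignment with a Karlin-Altschul significance approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .simulate import revcomp

__all__ = [
    "TrimSpec",
    "ScreenSpec",
    "CleanEST",
    "StageReport",
    "quality_trim",
    "strip_vector",
    "trim_polyat",
    "screen_contamination",
    "run_preprocess",
]


@dataclass
class TrimSpec:
    """Parameters of the trimming stages."""

    quality_error_cutoff: float = 0.01
    vector_seqs: tuple[str, ...] = ()
    max_vector_mismatch: float = 0.20  # mismatch fraction over aligned columns
    min_vector_hit: int = 16           # shortest vector match acted upon
    polyat_min_run: int = 10
    polyat_max_mismatch: int = 1
    min_length: int = 50

    def __post_init__(self):
        if not (0.0 < self.quality_error_cutoff < 1.0):
            raise ValueError("quality_error_cutoff must be in (0, 1)")
        if not (0.0 <= self.max_vector_mismatch < 1.0):
            raise ValueError("max_vector_mismatch must be in [0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class ScreenSpec:
    """Contamination screen: scoring, identity and significance thresholds.

    Significance uses the Karlin-Altschul approximation
    E = K * m * n * exp(-lambda * S) with the classic ungapped nucleotide
    constants for +1/-2 scoring (lambda = 1.33, K = 0.621); m is the query
    length and n the total contaminant database length.
    """

    contaminant_seqs: dict[str, str] = field(default_factory=dict)
    min_identity: float = 0.90
    max_evalue: float = 1e-10
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    ka_lambda: float = 1.33
    ka_k: float = 0.621

    def __post_init__(self):
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@dataclass
class CleanEST:
    id: str
    sequence: str
    kept_interval: tuple[int, int]  # offsets into the raw read
    stage_log: list[str] = field(default_factory=list)


@dataclass
class StageReport:
    """Per-stage read accounting for the cleaning pipeline."""

    n_input: int = 0
    discarded: dict[str, int] = field(default_factory=lambda: {
        "quality": 0, "vector": 0, "polyat": 0, "contamination": 0, "length": 0})
    n_survivors: int = 0

    def conserved(self) -> bool:
        return self.n_input == self.n_survivors + sum(self.discarded.values())

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [("input", self.n_input)]
        rows += [(f"discarded_{k}", v) for k, v in self.discarded.items()]
        rows.append(("survivors", self.n_survivors))
        return rows


# ---------------------------------------------------------------------------
# quality trimming
# ---------------------------------------------------------------------------

def quality_trim(sequence: str, qualities, cutoff: float = 0.01
                 ) -> tuple[int, int]:
    """Maximum-scoring segment of per-base scores (cutoff - p_err).

    Returns the kept interval [start, end); (0, 0) when every prefix scores
    negative (all-bad read).  Among equal-scoring segments the leftmost
    (then shortest) is returned.
    """
    qualities = np.asarray(qualities, dtype=float)
    if len(qualities) != len(sequence):
        raise ValueError(
            f"sequence length {len(sequence)} != qualities length {len(qualities)}")
    scores = cutoff - qualities
    best = (0.0, 0, 0)  # (score, start, end) — score strictly better to replace
    run_start, run_score = 0, 0.0
    for i, s in enumerate(scores):
        if run_score < 0.0:
            run_start, run_score = i, 0.0
        run_score += s
        if run_score > best[0] + 1e-12:
            best = (run_score, run_start, i + 1)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# vector / adaptor stripping
# ---------------------------------------------------------------------------

def _local_aligner(match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _best_local_hit(query: str, target: str, aligner):
    """Best local alignment of query inside target.

    Returns (score, target_interval, n_columns, n_matches) or None.
    """
    if not query or not target:
        return None
    alns = aligner.align(target, query)
    if len(alns) == 0 or alns[0].score <= 0:
        return None
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    n_match = 0
    cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            cols += (ts - prev_t) + (qs - prev_q)  # gap columns
        for a, b in zip(target[ts:te], query[qs:qe]):
            cols += 1
            if a == b:
                n_match += 1
        prev_t, prev_q = te, qe
    t_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return float(aln.score), t_iv, cols, n_match


def strip_vector(sequence: str, spec: TrimSpec) -> tuple[str, list[dict]]:
    """Remove vector/adaptor occurrences.

    Any occurrence with a per-occurrence mismatch fraction <= the allowed
    maximum is removed together with everything on its shorter-flank side
    (for a terminal hit: everything outward of it); the longer flank is
    retained.  Both strands of every vector sequence are searched and the
    procedure repeats until no qualifying hit remains.
    """
    report: list[dict] = []
    if not spec.vector_seqs:
        return sequence, report
    # mild mismatch penalty so the local hit extends through scattered
    # substitutions instead of truncating at them
    aligner = _local_aligner(match=1, mismatch=-1)
    queries = []
    for v in spec.vector_seqs:
        queries.append(v)
        queries.append(revcomp(v))
    seq = sequence
    for _ in range(10):  # safety bound; real reads need 1-2 rounds
        best = None
        for q in queries:
            hit = _best_local_hit(q, seq, aligner)
            if hit is None:
                continue
            score, (ts, te), cols, n_match = hit
            mism_frac = 1.0 - n_match / cols
            if cols < spec.min_vector_hit or mism_frac > spec.max_vector_mismatch:
                continue
            if best is None or score > best[0]:
                best = (score, ts, te, cols, mism_frac)
        if best is None:
            break
        _, ts, te, cols, mism_frac = best
        left, right = ts, len(seq) - te
        if left >= right:
            kept, removed = seq[:ts], (ts, len(seq))
        else:
            kept, removed = seq[te:], (0, te)
        report.append({"interval": removed, "columns": cols,
                       "mismatch_fraction": round(mism_frac, 4),
                       "kept_side": "left" if left >= right else "right"})
        seq = kept
        if not seq:
            break
    return seq, report


# ---------------------------------------------------------------------------
# polyA/T removal
# ---------------------------------------------------------------------------

def _qualifying_runs(seq: str, base: str, min_run: int, max_mismatch: int):
    """Maximal windows of `base` with <= max_mismatch interruptions,
    length >= min_run, trimmed to start/end on `base`."""
    import bisect
    n = len(seq)
    # prefix[i] = number of non-`base` characters in seq[:i]
    prefix = [0] * (n + 1)
    for i, ch in enumerate(seq):
        prefix[i + 1] = prefix[i] + (ch != base)
    runs = []
    for i in range(n):
        if seq[i] != base:
            continue
        # furthest j with <= max_mismatch interruptions in seq[i:j]
        j = bisect.bisect_right(prefix, prefix[i] + max_mismatch, lo=i + 1) - 1
        b = j
        while b > i and seq[b - 1] != base:
            b -= 1
        if b - i >= min_run:
            runs.append((i, b))
    # merge overlapping windows
    merged = []
    for a, b in sorted(runs):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def trim_polyat(sequence: str, spec: TrimSpec) -> str:
    """Remove polyA/T runs together with the flank proximal to the nearer
    read end; at most one removal per end."""
    seq = sequence
    n = len(seq)
    if n == 0:
        return seq
    runs = []
    for base in "AT":
        runs.extend(_qualifying_runs(seq, base, spec.polyat_min_run,
                                     spec.polyat_max_mismatch))
    if not runs:
        return seq
    # assign each run to its nearer end by midpoint
    cut5 = 0        # remove [0, cut5)
    cut3 = n        # remove [cut3, n)
    for a, b in runs:
        if (a + b) / 2.0 < n / 2.0:
            cut5 = max(cut5, b)
        else:
            cut3 = min(cut3, a)
    if cut5 >= cut3:
        return ""
    return seq[cut5:cut3]


# ---------------------------------------------------------------------------
# contamination screen
# ---------------------------------------------------------------------------

def screen_contamination(sequence: str, spec: ScreenSpec) -> dict:
    """Decide keep/discard against the contaminant database.

    Discard iff the best local alignment to any contaminant reaches both
    identity >= min_identity (over aligned columns, gaps included) and
    E-value <= max_evalue.  Empty database always keeps.
    """
    result = {"keep": True, "best_name": None, "identity": 0.0,
              "evalue": float("inf"), "score": 0.0}
    if not spec.contaminant_seqs or not sequence:
        return result
    aligner = _local_aligner(spec.match, spec.mismatch,
                             spec.gap_open, spec.gap_extend)
    db_len = sum(len(s) for s in spec.contaminant_seqs.values())
    best = None
    for name, cseq in spec.contaminant_seqs.items():
        for strand_seq in (cseq, revcomp(cseq)):
            hit = _best_local_hit(sequence, strand_seq, aligner)
            if hit is None:
                continue
            score, _iv, cols, n_match = hit
            if best is None or score > best[0]:
                best = (score, name, cols, n_match)
    if best is None:
        return result
    score, name, cols, n_match = best
    identity = n_match / cols if cols else 0.0
    evalue = spec.ka_k * len(sequence) * db_len * float(
        np.exp(-spec.ka_lambda * score))
    result.update(best_name=name, identity=identity, evalue=evalue, score=score)
    if identity >= spec.min_identity and evalue <= spec.max_evalue:
        result["keep"] = False
    return result


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_preprocess(reads: dict[str, str], qualities: dict[str, np.ndarray],
                   trim: TrimSpec, screen: ScreenSpec | None = None
                   ) -> tuple[list[CleanEST], StageReport]:
    """Apply quality -> vector -> polyA/T -> contamination -> length.

    ``reads`` maps id -> sequence; ``qualities`` maps id -> per-base error
    probabilities (reads without qualities skip the quality stage).
    """
    report = StageReport(n_input=len(reads))
    out: list[CleanEST] = []
    for rid, raw in reads.items():
        log = []
        start, end = 0, len(raw)
        if rid in qualities and len(qualities[rid]) == len(raw):
            start, end = quality_trim(raw, qualities[rid],
                                      trim.quality_error_cutoff)
            log.append(f"quality:{start}-{end}")
        seq = raw[start:end]
        if not seq:
            report.discarded["quality"] += 1
            continue

        seq, vec_report = strip_vector(seq, trim)
        if vec_report:
            log.append(f"vector:{len(vec_report)}hits")
        if not seq:
            report.discarded["vector"] += 1
            continue

        trimmed = trim_polyat(seq, trim)
        if trimmed != seq:
            log.append("polyat")
        seq = trimmed
        if not seq:
            report.discarded["polyat"] += 1
            continue

        if screen is not None:
            verdict = screen_contamination(seq, screen)
            if not verdict["keep"]:
                report.discarded["contamination"] += 1
                continue

        if len(seq) < trim.min_length:
            report.discarded["length"] += 1
            continue

        # kept_interval: offsets of the final slice within the raw read;
        # every stage keeps one contiguous slice, so the slice re-locates
        # inside the quality window
        off = raw.find(seq, start, end)
        if off < 0:  # unreachable unless a stage broke contiguity
            off = start
        out.append(CleanEST(rid, seq, (off, off + len(seq)), log))
    report.n_survivors = len(out)
    return out, report
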