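"""EST-count over-representation analysis.

Non-normalized cDNA libraries preserve transcript abundance, so per-gene
EST counts are a semi-quantitative expression measure.  Three analyses run
on the gene x library count matrix:

* a listing of strongly supported genes (row sum >= 50 ESTs) and the
  supporting-EST histogram;
* a per-gene chi-square test of counts against library-size expectations,
  with the p-value simulated by Monte-Carlo multinomial replicates
  (p = (1 + #{replicate stat >= observed}) / (B + 1));
* an exact two-sided binomial test (minimum-likelihood method) for
  monokaryon-versus-dikaryon strain bias.

The raw 1e-5 significance threshold mirrors the study's usage; a
Benjamini-Hochberg column is available for reporting but not used for
flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "OverrepConfig",
    "TestResult",
    "build_counts",
    "support_histogram",
    "chisq_stage_test",
    "binom_strain_test",
    "pathway_counts",
    "run_overrep",
]


@dataclass
class OverrepConfig:
    min_support: int = 50
    alpha: float = 1e-5
    mc_replicates: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.mc_replicates < int(np.ceil(1.0 / self.alpha)):
            raise ValueError(
                "mc_replicates must be >= ceil(1/alpha), otherwise the "
                "smallest attainable simulated p cannot cross alpha")


@dataclass
class CountMatrix:
    """Integer EST counts per gene (rows) per library (columns)."""

    counts: pd.DataFrame                      # genes x libraries
    library_meta: pd.DataFrame | None = None  # index=library: day, karyotype

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integers")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class TestResult:
    gene: str
    method: str  # chisq_mc | binomial
    statistic: float
    p_value: float
    flagged: bool
    note: str = ""


def build_counts(assignments: dict[str, tuple[str, str]],
                 libraries: list[str],
                 library_meta: pd.DataFrame | None = None) -> CountMatrix:
    """Counts from EST -> (gene, library) assignments.

    Each EST may support at most one gene; a duplicate EST id is an
    integrity error (enforced by the dict input upstream of this call via
    its construction — a list input is checked here).
    """
    if isinstance(assignments, list):
        seen: set[str] = set()
        amap = {}
        for est, gene, lib in assignments:
            if est in seen:
                raise ValueError(f"EST {est} assigned more than once")
            seen.add(est)
            amap[est] = (gene, lib)
        assignments = amap
    genes = sorted({g for g, _ in assignments.values()})
    mat = pd.DataFrame(0, index=genes, columns=list(libraries), dtype=int)
    for est, (gene, lib) in assignments.items():
        if lib not in mat.columns:
            raise ValueError(f"unknown library {lib!r} for EST {est}")
        mat.loc[gene, lib] += 1
    return CountMatrix(mat, library_meta)


def support_histogram(matrix: CountMatrix, bin_edges: list[int] | None = None,
                      min_support: int = 50) -> dict:
    """Bin genes by row sum; edges must partition [0, inf).

    Returns per-bin gene counts plus the number of genes at or above
    ``min_support`` supporting ESTs.
    """
    row = matrix.counts.sum(axis=1).to_numpy()
    if bin_edges is None:
        bin_edges = [0, 1, 50, 100, 150, 200, 250, 300, 350, 400]
    edges = list(bin_edges)
    if sorted(set(edges)) != edges or edges[0] != 0:
        raise ValueError("bin edges must be strictly increasing from 0")
    labels = [f"{a}-{b - 1}" if b - a > 1 else f"{a}"
              for a, b in zip(edges, edges[1:])] + [f">={edges[-1]}"]
    idx = np.searchsorted(edges, row, side="right") - 1
    hist = {lab: int(np.sum(idx == i)) for i, lab in enumerate(labels)}
    return {"bins": hist,
            "genes_at_or_above": int(np.sum(row >= min_support)),
            "min_support": min_support}


def chisq_stage_test(gene: str, gene_row, library_totals,
                     B: int = 200_000, seed: int = 0,
                     alpha: float = 1e-5) -> TestResult:
    """Chi-square statistic with Monte-Carlo simulated p-value.

    Expected counts are proportional to library totals; the null draws
    multinomial replicates of the row total on those proportions and
    p = (1 + #{replicate >= observed}) / (B + 1).
    """
    obs = np.asarray(gene_row, dtype=float)
    totals = np.asarray(library_totals, dtype=float)
    n = obs.sum()
    if n <= 0:
        return TestResult(gene, "chisq_mc", float("nan"), float("nan"),
                          False, note="zero row: skipped")
    p = totals / totals.sum()
    expected = n * p
    stat = float(((obs - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = 50_000
    done = 0
    while done < B:
        m = min(chunk, B - done)
        reps = rng.multinomial(int(n), p, size=m)
        rep_stat = (((reps - expected) ** 2) / expected).sum(axis=1)
        exceed += int(np.sum(rep_stat >= stat - 1e-12))
        done += m
    pval = (1.0 + exceed) / (B + 1.0)
    return TestResult(gene, "chisq_mc", stat, pval, pval < alpha)


def binom_strain_test(gene: str, k_one_strain: int, n: int, p0: float,
                      alpha: float = 1e-5) -> TestResult:
    """Exact two-sided binomial test, minimum-likelihood method: the
    p-value sums Pr(j) over all outcomes j no more likely than k."""
    if not (0 <= k_one_strain <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    res = stats.binomtest(k_one_strain, n, p0, alternative="two-sided")
    pval = float(min(res.pvalue, 1.0))
    return TestResult(gene, "binomial", float(k_one_strain), pval,
                      pval < alpha)


def pathway_counts(matrix: CountMatrix, gene_subset: list[str],
                   library_subset: list[str]) -> tuple[int, int]:
    """(ESTs of the gene subset in the named libraries, ESTs of the gene
    subset across all libraries)."""
    unknown_g = [g for g in gene_subset if g not in matrix.counts.index]
    unknown_l = [l for l in library_subset if l not in matrix.counts.columns]
    if unknown_g:
        raise ValueError(f"unknown genes: {unknown_g}")
    if unknown_l:
        raise ValueError(f"unknown libraries: {unknown_l}")
    if not gene_subset:
        return (0, 0)
    sub = matrix.counts.loc[list(gene_subset)]
    return (int(sub[list(library_subset)].values.sum()),
            int(sub.values.sum()))


def run_overrep(matrix: CountMatrix, config: OverrepConfig | None = None,
                monokaryon_libs: list[str] | None = None,
                screen_alpha: float = 1e-3,
                screen_B: int = 2000) -> pd.DataFrame:
    """Full per-gene analysis table.

    Chi-square Monte-Carlo p-values are computed in two passes: a cheap
    screen with ``screen_B`` replicates for every gene, then the full
    ``config.mc_replicates`` only for genes passing the screen (others
    cannot reach the reporting threshold).
    """
    config = config or OverrepConfig()
    totals = matrix.library_totals
    if monokaryon_libs is None and matrix.library_meta is not None:
        monokaryon_libs = list(
            matrix.library_meta.index[
                matrix.library_meta["karyotype"] == "monokaryon"])
    mono = [l for l in (monokaryon_libs or []) if l in matrix.libraries]
    p_mono = (float(totals[mono].sum()) / float(totals.sum())) if mono else None
    rows = []
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 * len(matrix.genes))
    for i, g in enumerate(matrix.genes):
        row = matrix.counts.loc[g]
        n = int(row.sum())
        screen = chisq_stage_test(g, row, totals, B=screen_B,
                                  seed=int(seeds[2 * i]), alpha=config.alpha)
        if n > 0 and screen.p_value <= screen_alpha:
            chis = chisq_stage_test(g, row, totals, B=config.mc_replicates,
                                    seed=int(seeds[2 * i + 1]),
                                    alpha=config.alpha)
        else:
            chis = screen
        rec = {"gene": g, "row_total": n,
               **{f"n_{l}": int(row[l]) for l in matrix.libraries},
               "chisq_stat": chis.statistic, "chisq_p": chis.p_value,
               "chisq_flagged": bool(chis.flagged),
               "well_supported": n >= config.min_support}
        if p_mono is not None and n > 0:
            k = int(row[mono].sum())
            bres = binom_strain_test(g, k, n, p_mono, alpha=config.alpha)
            rec["binom_k_mono"] = k
            rec["binom_p"] = bres.p_value
            rec["binom_flagged"] = bool(bres.flagged)
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("gene")
    if "chisq_p" in df:
        mask = df["chisq_p"].notna()
        bh = np.full(len(df), np.nan)
        if mask.any():
            bh[mask.to_numpy()] = stats.false_discovery_control(
                df.loc[mask, "chisq_p"].to_numpy())
        df["chisq_p_bh"] = bh
    return df
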