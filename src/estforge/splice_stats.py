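"""Cassette-exon fraction statistics and the variant-EST index.

The CE fraction CE/(CE+RI) discriminates exon-definition from
intron-definition splice-site recognition: mutating a splice site under
intron definition tends to retain the intron (RI), under exon definition to
skip the exon (CE), so ID-dominated genomes show low CE fractions.  A
stretch of consecutively skipped exons (CSE) has no agreed counting rule,
so three policies are computed: each skipped exon counted separately
(``each_exon``), a stretch collapsed to one event (``stretch_as_one``), and
stretches excluded entirely (``exclude_cse``).

The expected CE fraction under the cross-species linear model is
y = 0.84 x, where x is the fraction of a genome's (predicted-gene) introns
longer than 200 bases — long introns favour exon definition.

The VE index (splice-variant genes / sequenced ESTs) normalizes variant
discovery by sequencing depth for cross-project comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from .splice_events import SpliceEvent

__all__ = [
    "CEFractionReport",
    "VEIndex",
    "ce_fraction",
    "expected_ce_fraction",
    "ve_index",
    "fraction_long_introns",
]

POLICIES = ("each_exon", "stretch_as_one", "exclude_cse")
#: Slope of the cross-species regression of CE fraction on the fraction of
#: introns > 200 bases (intercept 0).
MODEL_SLOPE = 0.84
LONG_INTRON_BASES = 200


@dataclass
class CEFractionReport:
    policy: str
    ce_count: int
    ri_count: int
    fraction: float | None
    frac_long_introns: float | None = None
    expected_fraction: float | None = None

    @property
    def defined(self) -> bool:
        return self.fraction is not None

    def display(self, decimals: int) -> str:
        return "undefined" if self.fraction is None else \
            f"{round(self.fraction, decimals):.{decimals}f}"


@dataclass
class VEIndex:
    n_variant_genes: int
    n_ests: int
    index: float

    def display(self, decimals: int = 3) -> str:
        return f"{round(self.index, decimals):.{decimals}f}"


def ce_fraction(skipped_events: list[SpliceEvent] | list[int],
                ri_exon_count: int, policy: str = "each_exon",
                frac_long_introns: float | None = None) -> CEFractionReport:
    """CE fraction under one CSE counting policy.

    ``skipped_events`` is the reliable CE/CSE event list (or simply their
    exon counts).  Policies: ``each_exon`` sums exon counts;
    ``stretch_as_one`` counts events; ``exclude_cse`` counts only
    single-exon events.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    exon_counts = [
        ev.exon_count if isinstance(ev, SpliceEvent) else int(ev)
        for ev in skipped_events]
    if any(c < 1 for c in exon_counts):
        raise ValueError("exon counts must be >= 1")
    if policy == "each_exon":
        ce = sum(exon_counts)
    elif policy == "stretch_as_one":
        ce = len(exon_counts)
    else:
        ce = sum(1 for c in exon_counts if c == 1)
    denom = ce + ri_exon_count
    frac = ce / denom if denom > 0 else None
    expected = (expected_ce_fraction(frac_long_introns)
                if frac_long_introns is not None else None)
    return CEFractionReport(policy, ce, ri_exon_count, frac,
                            frac_long_introns, expected)


def expected_ce_fraction(frac_long_introns: float) -> float:
    """Linear-model expectation 0.84 x for x = fraction of introns > 200 b."""
    if not (0.0 <= frac_long_introns <= 1.0):
        raise ValueError("frac_long_introns must be in [0, 1]")
    return MODEL_SLOPE * frac_long_introns


def ve_index(n_variant_genes: int, n_ests: int) -> VEIndex:
    """Splice-variant genes per sequenced EST."""
    if n_ests <= 0:
        raise ValueError("n_ests must be positive")
    if n_variant_genes < 0:
        raise ValueError("n_variant_genes must be >= 0")
    return VEIndex(n_variant_genes, n_ests, n_variant_genes / n_ests)


def fraction_long_introns(intron_lengths, threshold: int = LONG_INTRON_BASES
                          ) -> float:
    """Fraction of intron lengths exceeding ``threshold`` bases."""
    lengths = list(intron_lengths)
    if not lengths:
        raise ValueError("no introns supplied")
    return sum(1 for x in lengths if x > threshold) / len(lengths)
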