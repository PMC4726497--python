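"""Genome-wide tripartite motif screen and set-overlap accounting.

Screens the annotated gene universe for transcripts whose 3'UTR carries
all of CPE, CPSF and NRE, then filters sequentially for expressed and
Cnot7-anticorrelated transcripts, reporting counts and percentages at
each step plus exact Venn partitions for 2- or 3-set overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

TRIPARTITE_MOTIFS = ("CPE", "CPSF", "NRE")


def genes_with_all(annotation: pd.DataFrame, motif_names: list[str]) -> set[str]:
    """Genes with at least one site of every named motif (vacuously all
    genes for an empty motif list)."""
    unknown = [m for m in motif_names if m not in annotation.columns]
    if unknown:
        raise KeyError(f"unknown motif names: {unknown!r}")
    mask = pd.Series(True, index=annotation.index)
    for m in motif_names:
        mask &= annotation[m] >= 1
    return set(annotation.index[mask])


def venn(sets: list[set[str]]) -> dict[str, int]:
    """Exclusive-region counts for 2 or 3 sets.

    Keys for 3 sets: A, B, C (exclusive), AB, AC, BC, ABC, union; for 2
    sets: A, B, AB, union. Regions always sum to the union size.
    """
    if len(sets) == 2:
        a, b = sets
        ab = a & b
        return {
            "A": len(a - b),
            "B": len(b - a),
            "AB": len(ab),
            "union": len(a | b),
        }
    if len(sets) == 3:
        a, b, c = sets
        abc = a & b & c
        return {
            "A": len(a - b - c),
            "B": len(b - a - c),
            "C": len(c - a - b),
            "AB": len((a & b) - c),
            "AC": len((a & c) - b),
            "BC": len((b & c) - a),
            "ABC": len(abc),
            "union": len(a | b | c),
        }
    raise ValueError(f"venn supports 2 or 3 sets, got {len(sets)}")


def percent(k: int, n: int, decimals: int = 0) -> str:
    """Format 100*k/n rounded half-away-from-zero, e.g. (71, 149) -> '48%'."""
    if n <= 0:
        raise ValueError("percentage denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"count {k} outside [0, {n}]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value}%"


@dataclass(frozen=True)
class ScreenReport:
    """Sequential filter-chain counts for the tripartite genome screen."""

    n_genome: int
    n_tripartite: int
    n_expressed_tripartite: int
    n_final: int
    final_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        chain = (self.n_genome, self.n_tripartite, self.n_expressed_tripartite, self.n_final)
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError(f"filter chain must be non-increasing: {chain}")

    def percentages(self, decimals: int = 1) -> dict[str, str]:
        return {
            "tripartite_of_genome": percent(self.n_tripartite, self.n_genome, decimals),
            "expressed_of_tripartite": percent(
                self.n_expressed_tripartite, self.n_tripartite, decimals
            )
            if self.n_tripartite
            else "0.0%",
            "final_of_expressed": percent(
                self.n_final, self.n_expressed_tripartite, decimals
            )
            if self.n_expressed_tripartite
            else "0.0%",
        }

    def as_dict(self) -> dict:
        return {
            "n_genome": self.n_genome,
            "n_tripartite": self.n_tripartite,
            "n_expressed_tripartite": self.n_expressed_tripartite,
            "n_final": self.n_final,
            "percentages": self.percentages(),
        }


def screen(
    annotation: pd.DataFrame,
    expressed: set[str],
    anticorrelated: set[str],
    motif_names: tuple[str, ...] = TRIPARTITE_MOTIFS,
) -> ScreenReport:
    """Tripartite screen: all-motif genes -> expressed -> anticorrelated."""
    universe = set(annotation.index)
    for name, s in (("expressed", expressed), ("anticorrelated", anticorrelated)):
        extra = s - universe
        if extra:
            raise ValueError(
                f"{name} genes absent from annotation: {sorted(extra)[:5]!r}"
            )
    tri = genes_with_all(annotation, list(motif_names))
    expr_tri = tri & expressed
    final = expr_tri & anticorrelated
    return ScreenReport(
        n_genome=len(universe),
        n_tripartite=len(tri),
        n_expressed_tripartite=len(expr_tri),
        n_final=len(final),
        final_genes=tuple(sorted(final)),
    )


def detect_expressed(values: pd.DataFrame, quantile: float = 0.25) -> set[str]:
    """Detection rule for 'expressed' genes: mean abundance above the given
    quantile of per-gene means (default 25th percentile)."""
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    means = values.mean(axis=1)
    return set(means.index[means > means.quantile(quantile)])
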