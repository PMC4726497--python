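"""3'UTR motif scanning.

Maps every occurrence of degenerate RBP motifs on the sense strand of
3'UTR sequences. Coordinates are 0-based half-open; overlapping matches
are all reported (no exclusion rule), and only the given strand is
scanned — 3'UTRs are mRNA features, so there is no reverse-complement
search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .motifs import MotifDefinition

VALID_SEQ_CHARS = frozenset("ACGUN")


@dataclass(frozen=True)
class UtrRecord:
    """One gene's 3'UTR sequence over the RNA alphabet (T normalized to U)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        seq = self.sequence.upper().replace("T", "U")
        if not seq:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(seq) - VALID_SEQ_CHARS
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid characters {sorted(bad)!r} "
                "(expected A/C/G/U/N; T is accepted and normalized)"
            )
        object.__setattr__(self, "sequence", seq)


class MotifSite(NamedTuple):
    gene_id: str
    motif_name: str
    start: int  # 0-based
    end: int  # half-open exclusive
    matched: str


def scan_sequence(utr: UtrRecord, motif: MotifDefinition) -> list[MotifSite]:
    """All sites of ``motif`` in ``utr``, overlapping included, sorted by start.

    Multiple patterns of one motif are scanned independently; a window
    matching two patterns of the same motif is reported once per pattern
    only if the matched subsequences differ in extent (identical
    (start, end) duplicates are collapsed).
    """
    seq = utr.sequence
    seen: set[tuple[int, int]] = set()
    sites: list[MotifSite] = []
    for pat in motif.compiled:
        for m in pat.finditer(seq):
            start = m.start()
            matched = m.group(1)
            key = (start, start + len(matched))
            if key in seen:
                continue
            seen.add(key)
            sites.append(MotifSite(utr.gene_id, motif.name, key[0], key[1], matched))
    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def scan_all(
    utrs: Iterable[UtrRecord], motifs: Iterable[MotifDefinition]
) -> pd.DataFrame:
    """Site table over a UTR set: columns gene, motif, start, end, matched."""
    rows = [
        site
        for utr in utrs
        for motif in motifs
        for site in scan_sequence(utr, motif)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "motif_name", "start", "end", "matched"])


def annotate(
    utrs: list[UtrRecord], motifs: list[MotifDefinition]
) -> pd.DataFrame:
    """Per-gene motif annotation: gene x motif matrix of site counts.

    Every gene in the UTR set appears as a row (zero counts explicit);
    ``has_motif`` for a cell is simply ``count >= 1``. Duplicate gene ids
    are an error — the annotation is keyed by gene.
    """
    ids = [u.gene_id for u in utrs]
    dupes = {g for g in ids if ids.count(g) > 1} if len(set(ids)) != len(ids) else set()
    if dupes:
        raise ValueError(f"duplicate gene ids in UTR set: {sorted(dupes)!r}")
    names = [m.name for m in motifs]
    counts = {
        u.gene_id: [len(scan_sequence(u, m)) for m in motifs] for u in utrs
    }
    df = pd.DataFrame.from_dict(counts, orient="index", columns=names)
    df.index.name = "gene_id"
    return df.astype(int)


def has_motif(annotation: pd.DataFrame, motif_name: str) -> pd.Series:
    """Boolean presence vector for one motif over the annotated genes."""
    if motif_name not in annotation.columns:
        raise KeyError(f"motif {motif_name!r} not in annotation")
    return annotation[motif_name] >= 1
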