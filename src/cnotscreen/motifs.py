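"""Degenerate RNA motif definitions.

RNA-binding-protein (RBP) recognition elements in 3'UTRs are short,
degenerate sequences conventionally written with IUPAC nucleotide codes.
This module holds the motif vocabulary used throughout the pipeline: the
cytoplasmic polyadenylation element (CPE, bound by CPEB proteins), the
Pumilio binding element (PUM/PBE), the Nanos response element (NRE), the
cleavage/polyadenylation stimulation factor element (CPSF; the canonical
poly(A) signal hexamer), and the permissive/stringent AU-rich elements
(ARE).

Consensus strings for CPE, PUM, NRE and CPSF are literature-standard
defaults and are fully overridable via a YAML config, since published
consensi vary between studies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

# IUPAC nucleotide codes over the RNA alphabet. A code maps to the set of
# concrete bases it accepts; N in a *sequence* matches no code (conservative).
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

MIN_PATTERN_LENGTH = 4


class InvalidIupacError(ValueError):
    """Raised when a motif pattern contains a non-IUPAC character."""


def expand_iupac(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC-degenerate RNA pattern into an overlap-aware regex.

    The returned regex is a zero-width lookahead capturing the matched
    window, so ``finditer`` enumerates *every* start position including
    overlapping occurrences. Sequence ``N`` bases match no pattern code.

    Raises
    ------
    InvalidIupacError
        If any character is not a valid IUPAC RNA code; the message names
        the offending character and its 0-based position.
    """
    if not pattern:
        raise InvalidIupacError("empty motif pattern")
    parts = []
    for i, ch in enumerate(pattern.upper().replace("T", "U")):
        try:
            bases = IUPAC_RNA[ch]
        except KeyError:
            raise InvalidIupacError(
                f"invalid IUPAC RNA code {ch!r} at position {i} in pattern {pattern!r}"
            ) from None
        parts.append("[" + "".join(sorted(bases)) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def pattern_matches(pattern: str, word: str) -> bool:
    """True iff ``word`` (concrete RNA) satisfies the degenerate ``pattern``."""
    if len(word) != len(pattern):
        return False
    return all(b in IUPAC_RNA[p] for p, b in zip(pattern.upper(), word.upper()))


@dataclass(frozen=True)
class MotifDefinition:
    """A named RBP motif given as one or more IUPAC-degenerate RNA strings."""

    name: str
    patterns: tuple[str, ...]
    _compiled: tuple[re.Pattern[str], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("motif name must be non-empty")
        if not self.patterns:
            raise ValueError(f"motif {self.name!r} has no patterns")
        norm = []
        for p in self.patterns:
            p = p.upper().replace("T", "U")
            if len(p) < MIN_PATTERN_LENGTH:
                raise ValueError(
                    f"motif {self.name!r}: pattern {p!r} shorter than "
                    f"{MIN_PATTERN_LENGTH} nt"
                )
            norm.append(p)
        object.__setattr__(self, "patterns", tuple(norm))
        object.__setattr__(self, "_compiled", tuple(expand_iupac(p) for p in norm))

    @property
    def compiled(self) -> tuple[re.Pattern[str], ...]:
        return self._compiled

    @property
    def max_length(self) -> int:
        return max(len(p) for p in self.patterns)


# Literature-standard consensus defaults (overridable via config):
#  CPE  - U-rich CPEB element, UUUUUAU with the common UUUUAAU variant
#  PUM  - Pumilio response element UGUAHAUA
#  NRE  - Nanos response element core AUUGUA
#  CPSF - canonical poly(A) signal AAUAAA
#  ARE  - permissive pentamer AUUUA; stringent nonamer UUAUUUAUU
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("CPE", ("UUUUUAU", "UUUUAAU")),
    MotifDefinition("PUM", ("UGUAHAUA",)),
    MotifDefinition("NRE", ("AUUGUA",)),
    MotifDefinition("CPSF", ("AAUAAA",)),
    MotifDefinition("ARE_permissive", ("AUUUA",)),
    MotifDefinition("ARE_stringent", ("UUAUUUAUU",)),
)


def default_motifs() -> list[MotifDefinition]:
    return list(DEFAULT_MOTIFS)


def load_motif_config(path: str) -> list[MotifDefinition]:
    """Read a YAML motif config: mapping of name -> pattern or pattern list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"motif config {path!r} must be a non-empty mapping")
    motifs = []
    for name, patterns in raw.items():
        if isinstance(patterns, str):
            patterns = [patterns]
        motifs.append(MotifDefinition(str(name), tuple(patterns)))
    return motifs


def write_motif_config(motifs: list[MotifDefinition], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({m.name: list(m.patterns) for m in motifs}, fh, sort_keys=False)
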