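"""MORE/PORE/Sox-Oct element grammar, subtype nomenclature and scanning.

POU-factor dimers recognize palindromic DNA elements built from the 6-bp
half-site ATGnAT:

- MORE: half-site + reverse-complemented half-site, a perfect 12-bp
  palindrome when both half-sites share the same 4th base.  Subtypes are
  named by that base: MORE-C4 is the conventional ATGCATATGCAT, MORE-A4 the
  variant ATGAATATTCAT; composites carry one half-site of each subtype
  (e.g. MORE-A4C4, ATGAATATGCAT).
- MORE+1: the same architecture with a single unconstrained base inserted
  between the half-sites (13 bp).
- PORE: the pseudo-palindrome ATTTG aaatg CAAAT — two 5-bp POU half-sites
  around a 5-bp spacer that is itself part of the element.
- Sox/Oct: the composite of a Sox HMG site (CATTGTT) abutting the octamer
  (ATGCAAAT), bound cooperatively by Sox2 + Oct4.

Scanning is exact-match on both strands (the mining procedure counts
perfect matches only); an element identical to its own reverse complement
is reported once, on the plus strand.  Composite MORE labels are strand-
canonicalized so that A4C4 and its reverse complement C4A4 count as one
subtype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable

from Bio.Seq import reverse_complement

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "build_more",
    "build_pore",
    "build_sox_oct",
    "default_motif_set",
    "scan_sequence",
    "classify_element",
    "MORE_HALF_SITES",
]

_BASES = "ACGT"

#: the four MORE half-sites, keyed by their subtype-defining 4th base
MORE_HALF_SITES = {b: f"ATG{b}AT" for b in _BASES}

PORE_HALF_5P = "ATTTG"
PORE_HALF_3P = "CAAAT"
PORE_SPACER = "AAATG"
SOX_SITE = "CATTGTT"
OCTAMER = "ATGCAAAT"


@dataclass(frozen=True)
class MotifDefinition:
    """One scannable element: two half-sites around an optional spacer."""

    element_class: str  # MORE, MORE_PLUS1, PORE, SOX_OCT, SOX, OCTAMER
    subtype: str  # canonical label, e.g. "MORE-A4C4"
    half_site_5p: str
    half_site_3p: str
    spacer_len: int = 0
    spacer: str | None = None  # exact string, or None for unconstrained

    def __post_init__(self) -> None:
        if self.spacer is not None and len(self.spacer) != self.spacer_len:
            raise ValueError("spacer string must have length spacer_len")

    @property
    def length(self) -> int:
        return len(self.half_site_5p) + self.spacer_len + len(self.half_site_3p)

    @property
    def consensus(self) -> str:
        """Element string with N at unconstrained spacer positions."""
        mid = self.spacer if self.spacer is not None else "N" * self.spacer_len
        return self.half_site_5p + mid + self.half_site_3p

    def pattern(self) -> str:
        """Regex matching the element on the plus strand."""
        mid = self.spacer if self.spacer is not None else "[ACGT]" * self.spacer_len
        return re.escape(self.half_site_5p) + mid + re.escape(self.half_site_3p)

    def is_self_palindromic(self) -> bool:
        """True when plus- and minus-strand match sets coincide.

        Holds for exact palindromes and for patterns whose unconstrained
        spacer makes the reverse complement match the same strings (the
        homotypic MORE+1 case).
        """
        if self.spacer is None:
            return (
                reverse_complement(self.half_site_3p) == self.half_site_5p
                and reverse_complement(self.half_site_5p) == self.half_site_3p
            )
        return reverse_complement(self.consensus) == self.consensus


@dataclass(frozen=True)
class MotifHit:
    """An exact element occurrence; coordinates are 0-based half-open on +."""

    seq_id: str
    start: int
    end: int
    strand: str
    element_class: str
    subtype: str
    matched: str  # plus-strand slice

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def build_more(subtype4, insertion: int = 0) -> MotifDefinition:
    """Construct a MORE (or MORE+1) definition from its 4th-position base(s).

    ``subtype4`` is a single base for homotypic palindromes or an ordered
    pair of bases for composites carrying one half-site of each subtype.
    ``insertion=1`` builds the MORE+1 variant with one unconstrained base
    between the half-sites.  The element is H(n1) + [N] + revcomp(H(n2))
    with H(n) = ATGnAT.
    """
    if isinstance(subtype4, str) and len(subtype4) == 1:
        pair = (subtype4, subtype4)
    else:
        pair = tuple(subtype4)
    if len(pair) != 2 or any(b not in _BASES for b in pair):
        raise ValueError(f"subtype4 must be a base or pair of bases from {_BASES}")
    if insertion not in (0, 1):
        raise ValueError("insertion must be 0 or 1")
    b1, b2 = pair
    label_core = b1 + "4" if b1 == b2 else f"{b1}4{b2}4"
    cls = "MORE_PLUS1" if insertion else "MORE"
    prefix = "MORE+1" if insertion else "MORE"
    return MotifDefinition(
        element_class=cls,
        subtype=f"{prefix}-{label_core}",
        half_site_5p=MORE_HALF_SITES[b1],
        half_site_3p=reverse_complement(MORE_HALF_SITES[b2]),
        spacer_len=insertion,
        spacer=None,
    )


def build_pore(spacer: str | None = PORE_SPACER) -> MotifDefinition:
    """The PORE element; pass ``spacer=None`` to accept any 5-bp spacer."""
    return MotifDefinition("PORE", "PORE", PORE_HALF_5P, PORE_HALF_3P, 5, spacer)


def build_sox_oct(spacer_len: int = 0) -> MotifDefinition:
    """Sox HMG site + octamer composite; spacer 0-3 bp, unconstrained."""
    if not 0 <= spacer_len <= 3:
        raise ValueError("Sox/Oct spacer must be 0-3 bp")
    return MotifDefinition("SOX_OCT", "SOX_OCT", SOX_SITE, OCTAMER, spacer_len, None)


def default_motif_set() -> tuple[MotifDefinition, ...]:
    """The full mining grammar: every canonical MORE/MORE+1 subtype
    (composite pairs in alphabetical order so each is counted once), the
    PORE and the Sox/Oct composite."""
    defs = []
    for insertion in (0, 1):
        for b1, b2 in combinations_with_replacement(_BASES, 2):
            defs.append(build_more((b1, b2), insertion))
    defs.append(build_pore())
    defs.append(build_sox_oct())
    return tuple(defs)


def scan_sequence(
    seq: str,
    motifs: Iterable[MotifDefinition],
    seq_id: str = "",
) -> list[MotifHit]:
    """All exact element occurrences on both strands of ``seq``.

    Minus-strand occurrences are located by matching each definition's
    reverse-complement pattern against the plus strand, so coordinates
    always refer to the input sequence.  Self-palindromic elements are
    reported once with strand '+'.  Hits are sorted by start position, then
    end, then subtype; overlapping hits of different classes all appear.
    N in the input never matches.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for m in motifs:
        fwd = re.compile(f"(?=({m.pattern()}))")
        for match in fwd.finditer(seq):
            s = match.start(1)
            hits.append(
                MotifHit(seq_id, s, s + m.length, "+", m.element_class, m.subtype, match.group(1))
            )
        if not m.is_self_palindromic():
            rc_pattern = _revcomp_pattern(m)
            rev = re.compile(f"(?=({rc_pattern}))")
            for match in rev.finditer(seq):
                s = match.start(1)
                hits.append(
                    MotifHit(seq_id, s, s + m.length, "-", m.element_class, m.subtype, match.group(1))
                )
    hits.sort(key=lambda h: (h.start, h.end, h.subtype, h.strand))
    return hits


def _revcomp_pattern(m: MotifDefinition) -> str:
    mid = m.spacer
    rc_5p = reverse_complement(m.half_site_3p)
    rc_3p = reverse_complement(m.half_site_5p)
    rc_mid = reverse_complement(mid) if mid is not None else "[ACGT]" * m.spacer_len
    return re.escape(rc_5p) + (rc_mid if mid is not None else rc_mid) + re.escape(rc_3p)


def classify_element(element: str) -> str | None:
    """Canonical MORE subtype label of a 12/13-bp element, or None.

    Tries the half-site grammar on the element and on its reverse
    complement; when both read as composites the label uses the
    alphabetically smaller ordered pair, so a subtype and its reverse
    complement share one name.  Raises ``ValueError`` for other lengths.
    """
    element = element.upper()
    if len(element) not in (12, 13):
        raise ValueError("MORE elements are 12 bp, MORE+1 elements 13 bp")
    insertion = len(element) - 12

    def read_pair(s: str) -> tuple[str, str] | None:
        h1, h2 = s[:6], s[6 + insertion :]
        rc_h2 = reverse_complement(h2)
        for b1, site1 in MORE_HALF_SITES.items():
            if h1 != site1:
                continue
            for b2, site2 in MORE_HALF_SITES.items():
                if rc_h2 == site2:
                    return (b1, b2)
        return None

    candidates = []
    for strand_seq in (element, reverse_complement(element)):
        pair = read_pair(strand_seq)
        if pair is not None:
            candidates.append(pair)
    if not candidates:
        return None
    pair = min(candidates)
    b1, b2 = pair
    core = b1 + "4" if b1 == b2 else f"{b1}4{b2}4"
    prefix = "MORE+1" if insertion else "MORE"
    return f"{prefix}-{core}"
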