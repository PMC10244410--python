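"""Small nucleotide-sequence helpers shared across modules.

All sequences are handled internally as DNA (T, not U); RNA input such as
a UGUANAUA motif is normalized with :func:`normalize_motif`.
"""

from __future__ import annotations

import re

from .errors import ValidationError

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> the set of bases each covers.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: frozenset of bases -> smallest IUPAC code covering them.
BASES_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA sequence (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_motif(motif: str) -> str:
    """Upper-case, convert U to T and validate IUPAC letters."""
    motif = motif.upper().replace("U", "T")
    bad = set(motif) - set(IUPAC_BASES)
    if bad:
        raise ValidationError(f"invalid IUPAC letters in motif: {sorted(bad)}")
    return motif


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC motif into a character-class regex."""
    motif = normalize_motif(motif)
    parts = []
    for letter in motif:
        bases = "".join(sorted(IUPAC_BASES[letter]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_code(bases: frozenset[str] | set[str]) -> str:
    """Smallest IUPAC letter covering a non-empty set of A/C/G/T bases."""
    key = frozenset(bases)
    if key not in BASES_IUPAC:
        raise ValidationError(f"not a valid base set: {sorted(bases)}")
    return BASES_IUPAC[key]


def matches_iupac(seq: str, motif: str) -> bool:
    """True if ``seq`` matches the IUPAC ``motif`` exactly (same length)."""
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC_BASES[m] for b, m in zip(seq, normalize_motif(motif)))
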