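"""Small nucleotide-sequence helpers shared across modules.

Sequences are plain upper-case strings, always written 5'->3' on their own
strand. Only unambiguous bases (A/C/G/T) are allowed in primers and
templates; IUPAC ambiguity codes appear only in restriction-enzyme
recognition sites.
"""

from __future__ import annotations

import re

from .errors import InputError

DNA_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# IUPAC nucleotide codes -> the set of bases each matches.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def validate_dna(seq: str, what: str = "sequence") -> str:
    """Return ``seq`` upper-cased, or raise :class:`InputError`."""
    if not seq:
        raise InputError(f"{what} is empty")
    up = seq.upper()
    bad = set(up) - DNA_BASES
    if bad:
        raise InputError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return up


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_complementary(a: str, b: str) -> bool:
    """Watson-Crick pairing of two single bases."""
    return complement(a) == b


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def iupac_regex(site: str) -> re.Pattern[str]:
    """Compile an IUPAC recognition site into a regex over A/C/G/T."""
    parts = []
    for ch in site.upper():
        if ch not in IUPAC_CODES:
            raise InputError(f"unknown IUPAC nucleotide code {ch!r} in {site!r}")
        bases = IUPAC_CODES[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_reverse_complement(site: str) -> str:
    return site.upper().translate(_IUPAC_COMPLEMENT)[::-1]
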