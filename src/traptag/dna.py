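"""Small sequence utilities shared across the pipeline.

Everything here operates on plain upper-case DNA strings; coordinates
are 1-based fully-closed unless a function says otherwise.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

#: IUPAC degenerate base -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: restriction enzymes used for splinkerette digestion
ENZYME_SITES = {
    "BstYI": "RGATCY",
    "BglII": "AGATCT",
}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate pattern into a regex."""
    return re.compile("".join(
        b if len(IUPAC[b]) == 1 else "[" + IUPAC[b] + "]" for b in pattern
    ))


def iupac_words(pattern: str) -> list[str]:
    """Enumerate every concrete word matching an IUPAC pattern."""
    words = [""]
    for b in pattern:
        words = [w + c for w in words for c in IUPAC[b]]
    return words


def find_all(haystack: str, needle: str, overlap: bool = True) -> list[int]:
    """All 0-based start positions of exact occurrences of ``needle``."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1 if overlap else i + len(needle))
    return hits


def count_genome_hits(genome: dict[str, str], pattern: str) -> list[tuple[str, int, str]]:
    """Exact occurrences of ``pattern`` on both strands of a genome.

    Returns (scaffold, 1-based start on the plus strand, strand) tuples.
    Minus-strand hits report the plus-strand start of the matched window.
    """
    rc = revcomp(pattern)
    hits: list[tuple[str, int, str]] = []
    for name, seq in genome.items():
        for i in find_all(seq, pattern):
            hits.append((name, i + 1, "+"))
        if rc != pattern:
            for i in find_all(seq, rc):
                hits.append((name, i + 1, "-"))
        else:
            # palindromic pattern: plus-strand hits cover both strands
            pass
    return hits


def enzyme_site_positions(seq: str, enzyme: str) -> list[int]:
    """0-based start positions of a restriction enzyme's recognition site.

    Both BstYI (RGATCY) and BglII (AGATCT) recognition sequences are
    degenerate-palindromic, so a plus-strand scan covers both strands.
    """
    if enzyme not in ENZYME_SITES:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {sorted(ENZYME_SITES)}")
    return [m.start() for m in iupac_regex(ENZYME_SITES[enzyme]).finditer(seq)]
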