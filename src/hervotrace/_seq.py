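"""Low-level DNA/protein sequence primitives.

Six-frame translation here deliberately maps *every* codon containing an
``N`` to ``'X'`` instead of resolving ambiguity (e.g. ``GCN`` is *not*
collapsed to alanine): downstream peptide matching treats ``X`` as matching
nothing, so an ambiguous base can never support a peptide hit.
"""

from __future__ import annotations

import itertools

DNA_ALPHABET = frozenset("ACGTN")
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (translation table 1), TCAG codon order.
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA[i]
    for i, (a, b, c) in enumerate(itertools.product("TCAG", repeat=3))
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def normalize_dna(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}."""
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"non-IUPAC (or unsupported ambiguity) characters in DNA: {sorted(bad)}"
        )
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate ``dna`` in frame 0; trailing 1-2 bases ignored; N-codons -> X.

    Stop codons are kept as ``'*'``.
    """
    out = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def six_frame_translate(dna: str) -> dict[str, str]:
    """Return the six frame translations of ``dna``, stop symbols retained.

    Frames ``+1/+2/+3`` read the given sequence at offsets 0/1/2; frames
    ``-1/-2/-3`` read the reverse complement at offsets 0/1/2.
    """
    dna = normalize_dna(dna)
    rc = revcomp(dna)
    return {
        "+1": translate(dna),
        "+2": translate(dna[1:]),
        "+3": translate(dna[2:]),
        "-1": translate(rc),
        "-2": translate(rc[1:]),
        "-3": translate(rc[2:]),
    }


def extract_orfs(frame_translation: str, min_len: int = 1) -> list[tuple[str, int]]:
    """Maximal stop-free substrings of a frame translation.

    Returns ``(protein, amino-acid offset within the frame)`` pairs for every
    stretch between ``'*'`` symbols (and the sequence ends) of length at least
    ``min_len``.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    orfs: list[tuple[str, int]] = []
    offset = 0
    for chunk in frame_translation.split("*"):
        if len(chunk) >= min_len:
            orfs.append((chunk, offset))
        offset += len(chunk) + 1
    return orfs


def frame_direction(frame: str) -> str:
    """'+' for +1/+2/+3, '-' for -1/-2/-3."""
    if frame not in FRAMES:
        raise ValueError(f"unknown frame {frame!r}")
    return frame[0]


def frame_shift(frame: str) -> int:
    """0-based nucleotide offset at which the frame starts reading."""
    return int(frame[1]) - 1


def compose_strands(a: str, b: str) -> str:
    """Strand composition: equal signs give '+', opposite give '-'."""
    return "+" if a == b else "-"


def validate_peptide(seq: str) -> str:
    """Uppercase and validate a query peptide (standard 20 residues, len>=3)."""
    s = seq.upper()
    bad = set(s) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in peptide {seq!r}: {sorted(bad)}")
    if len(s) < 3:
        raise ValueError(f"peptide {seq!r} shorter than 3 residues")
    return s
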