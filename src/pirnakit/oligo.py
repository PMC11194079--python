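"""Helpers for editing-donor oligonucleotides with case-marked codons.

Donor sequences for codon replacement are conventionally written with the
edited codons in lowercase inside uppercase homology arms.  These helpers
recover the edited codons and check what they encode.
"""

from __future__ import annotations

import re

from Bio.Seq import Seq

_LOWER_RUN = re.compile(r"[acgtu]+")


def clean_sequence(seq: str) -> str:
    """Strip whitespace; keep case (it is meaningful here)."""
    return re.sub(r"\s+", "", seq)


def lowercase_codons(seq: str) -> list[str]:
    """Lowercase runs split into codons (each run must be a whole number).

    Runs are taken in order of appearance; a run of 3k bases yields k codons.
    """
    codons: list[str] = []
    for run in _LOWER_RUN.findall(clean_sequence(seq)):
        if len(run) % 3:
            raise ValueError(f"lowercase run {run!r} is not a whole number of codons")
        codons.extend(run[i : i + 3].upper() for i in range(0, len(run), 3))
    return codons


def count_edited_codons_encoding(seq: str, amino_acid: str) -> int:
    """Number of lowercase-marked codons translating to ``amino_acid``.

    ``amino_acid`` is a one-letter code, e.g. ``"K"`` for lysine.
    """
    return sum(
        1
        for codon in lowercase_codons(seq)
        if str(Seq(codon.replace("U", "T")).translate()) == amino_acid.upper()
    )
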