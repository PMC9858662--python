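"""Anticodon/codon algebra under the standard genetic code.

All sequences are handled in DNA notation (T, not U), written 5'→3'.
tRNA anticodons pair antiparallel with mRNA codons, so the codon decoded
by an anticodon is its reverse complement.  The standard code (NCBI
translation table 1) is the only table used; the three standard stop
codons (TAA, TAG, TGA) have no cognate amino acid, and their
reverse-complement anticodons (TTA, CTA, TCA) are reported as STOP.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "STOP",
    "IsotypeAssignment",
    "normalize_anticodon",
    "enumerate_anticodons",
    "anticodon_to_codon",
    "codon_table",
    "predict_isotype",
    "count_sense_codons",
    "stop_anticodons",
    "to_rna",
]

log = logging.getLogger(__name__)

STOP = "STOP"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


def normalize_anticodon(seq: str) -> str:
    """Canonicalize a 3-mer: uppercase, U→T.

    GtRNAdb mature sequences use the RNA alphabet; U is silently mapped
    to T (with a debug log note) so that all downstream computation runs
    in DNA space.

    Raises
    ------
    ValueError
        If the normalized sequence is not a 3-mer over {A,C,G,T}; the
        message names the offending character and its position.
    """
    s = seq.strip().upper()
    if "U" in s:
        log.debug("RNA alphabet input %r normalized to DNA", seq)
        s = s.replace("U", "T")
    if len(s) != 3:
        raise ValueError(f"anticodon must have length 3, got {len(s)}: {seq!r}")
    for i, ch in enumerate(s):
        if ch not in _ALPHABET:
            raise ValueError(
                f"invalid character {ch!r} at position {i} in anticodon {seq!r}"
            )
    return s


@dataclass(frozen=True)
class IsotypeAssignment:
    """Standard-code prediction for one anticodon."""

    anticodon: str
    predicted_isotype: str  # 3-letter amino-acid code, or STOP
    decoded_codon: str


def enumerate_anticodons() -> list[str]:
    """All 64 anticodon triplets, lexicographic (AAA … TTT)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=3)]


def anticodon_to_codon(anticodon: str) -> str:
    """Reverse complement: the mRNA codon (DNA notation) an anticodon decodes.

    The operation is an involution: applying it twice recovers the input.
    """
    return normalize_anticodon(anticodon).translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def codon_table() -> dict[str, str]:
    """Codon → 3-letter amino acid (or STOP), from the packaged table asset."""
    text = resources.files("trnaome.data").joinpath("codon_table.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split("\t")
        table[codon] = aa
    if len(table) != 64:
        raise RuntimeError(f"codon table asset is corrupt: {len(table)} entries")
    return table


def predict_isotype(anticodon: str) -> IsotypeAssignment:
    """Predict the amino acid carried by a tRNA from its anticodon alone.

    Stop-complement anticodons (TTA/CTA/TCA) yield STOP.  Annotation
    isotypes (e.g. Sec at TCA, Sup suppressors, iMet) always override
    this prediction downstream; the prediction is used to flag unusual
    isotype–anticodon combinations.
    """
    ac = normalize_anticodon(anticodon)
    codon = anticodon_to_codon(ac)
    return IsotypeAssignment(ac, codon_table()[codon], codon)


def count_sense_codons() -> int:
    """Number of amino-acid-coding codons: 64 minus the stop codons."""
    return sum(1 for aa in codon_table().values() if aa != STOP)


def stop_anticodons() -> frozenset[str]:
    """Anticodons whose decoded codon is a standard stop codon."""
    return frozenset(
        ac for ac in enumerate_anticodons()
        if codon_table()[anticodon_to_codon(ac)] == STOP
    )


def to_rna(seq: str) -> str:
    """Display transform to RNA notation (T→U). Never used in computation."""
    return seq.upper().replace("T", "U")
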