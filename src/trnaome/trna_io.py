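"""Readers and writers for tRNA annotation data.

Formats handled:

* tRNAscan-SE v2 tabular ``.out`` files (read and write).  The format has
  three header lines followed by whitespace-delimited columns: sequence
  name, tRNA number, begin, end, isotype, anticodon, intron begin, intron
  end, covariance-model score, and an optional note column.  Minus-strand
  loci are conveyed by file begin > end; this module normalizes
  immediately to begin ≤ end with an explicit strand so that all
  downstream arithmetic assumes one convention.  An extended dialect with
  semicolon-separated intron bounds (multiple introns per locus) is
  accepted.
* FASTA (via Biopython), with optional U→T normalization to DNA space.
* Genome metadata TSV (genome_id, species, domain, group, genome_size_mb,
  protein_coding_genes).
* BED6 export of loci (0-based half-open).

A locus is flagged as a pseudogene when its anticodon is undetermined
(``NNN``/``???``) — operationally, a locus detected without an assignable
anticodon — or when its note column mentions "pseudo".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .genetic_code import normalize_anticodon

__all__ = [
    "UNDETERMINED",
    "DOMAINS",
    "TRNALocus",
    "GenomeMetadata",
    "read_trnascan",
    "write_trnascan",
    "read_metadata",
    "write_metadata",
    "write_bed",
    "read_fasta",
    "write_fasta",
]

log = logging.getLogger(__name__)

#: Sentinel for loci with no assignable anticodon (tRNA pseudogenes).
UNDETERMINED = None

DOMAINS = ("Bacteria", "Archaea", "Eukarya")

_UNDET_TOKENS = {"NNN", "???"}


@dataclass
class TRNALocus:
    """One annotated tRNA gene locus, coordinates 1-based inclusive."""

    genome_id: str
    seq_name: str
    begin: int
    end: int
    strand: str  # '+' or '-'
    isotype: str
    anticodon: str | None  # UNDETERMINED (None) for pseudogenes
    intron_segments: list[tuple[int, int]] = field(default_factory=list)
    score: float = 0.0
    is_pseudogene: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError(
                f"locus {self.seq_name}:{self.begin}-{self.end} not normalized"
            )
        if self.gene_length <= 0:
            raise ValueError("locus has non-positive length")
        for b, e in self.intron_segments:
            if not (self.begin <= b <= e <= self.end):
                raise ValueError(
                    f"intron {b}-{e} outside locus {self.begin}-{self.end}"
                )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def gene_length(self) -> int:
        return self.end - self.begin + 1

    @property
    def intron_length(self) -> int:
        return sum(e - b + 1 for b, e in self.intron_segments)

    @property
    def mature_length(self) -> int:
        """Encoded mature length: gene length minus introns (CCA not added)."""
        return self.gene_length - self.intron_length

    @property
    def n_introns(self) -> int:
        return len(self.intron_segments)


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    species: str
    domain: str
    group: str
    genome_size_mb: float
    protein_coding_genes: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"unknown domain {self.domain!r} for {self.genome_id}; "
                f"expected one of {DOMAINS}"
            )
        if self.genome_size_mb <= 0:
            raise ValueError(f"non-positive genome size for {self.genome_id}")
        if self.protein_coding_genes < 0:
            raise ValueError(f"negative gene count for {self.genome_id}")


def _parse_intron_bounds(bstr: str, estr: str, line_no: int) -> list[tuple[int, int]]:
    begins = [int(x) for x in bstr.split(";")]
    ends = [int(x) for x in estr.split(";")]
    if len(begins) != len(ends):
        raise ValueError(f"line {line_no}: mismatched intron bound lists")
    return [(b, e) for b, e in zip(begins, ends) if not (b == 0 and e == 0)]


def read_trnascan(path: str | Path, genome_id: str | None = None) -> list[TRNALocus]:
    """Parse a tRNAscan-SE tabular ``.out`` file into normalized loci.

    ``genome_id`` defaults to the file stem.  Raises ``ValueError`` with
    the offending line number on malformed rows.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    loci: list[TRNALocus] = []
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines[3:], start=4):  # 3 header lines
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) < 9:
            raise ValueError(f"{path}: line {i}: expected >= 9 columns, got {len(tok)}")
        try:
            seq_name = tok[0]
            fbegin, fend = int(tok[2]), int(tok[3])
            isotype = tok[4]
            ac_raw = tok[5]
            introns = _parse_intron_bounds(tok[6], tok[7], i)
            score = float(tok[8])
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        note = " ".join(tok[9:]) if len(tok) > 9 else ""

        strand = "+"
        if fbegin > fend:
            strand = "-"
            fbegin, fend = fend, fbegin
            introns = [(min(b, e), max(b, e)) for b, e in introns]
        introns.sort()

        if ac_raw.upper() in _UNDET_TOKENS:
            anticodon = UNDETERMINED
        else:
            anticodon = normalize_anticodon(ac_raw)
        is_pseudo = anticodon is UNDETERMINED or "pseudo" in note.lower()
        if is_pseudo and anticodon is not UNDETERMINED:
            log.debug("%s line %d: pseudogene note on determined anticodon", path, i)

        try:
            loci.append(
                TRNALocus(
                    genome_id=gid,
                    seq_name=seq_name,
                    begin=fbegin,
                    end=fend,
                    strand=strand,
                    isotype=isotype,
                    anticodon=anticodon,
                    intron_segments=introns,
                    score=score,
                    is_pseudogene=is_pseudo,
                    note=note,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return loci


_HEADER = (
    "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
    "--------\t------\t-----\t----\t----\t-----\t-----\t----\t-----\t----\n"
)


def write_trnascan(loci: Iterable[TRNALocus], path: str | Path) -> None:
    """Serialize loci back to the tRNAscan-SE tabular dialect.

    Minus-strand loci are written with begin > end, inverting the
    normalization applied by :func:`read_trnascan` (round-trip stable).
    """
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for n, loc in enumerate(loci, start=1):
            b, e = loc.begin, loc.end
            introns = loc.intron_segments
            if loc.strand == "-":
                b, e = e, b
                introns = [(ie, ib) for ib, ie in introns]
            if introns:
                ibs = ";".join(str(x) for x, _ in introns)
                ies = ";".join(str(x) for _, x in introns)
            else:
                ibs = ies = "0"
            ac = loc.anticodon if loc.anticodon is not UNDETERMINED else "NNN"
            row = (
                f"{loc.seq_name}\t{n}\t{b}\t{e}\t{loc.isotype}\t{ac}"
                f"\t{ibs}\t{ies}\t{loc.score:.1f}"
            )
            if loc.note:
                row += f"\t{loc.note}"
            fh.write(row + "\n")


_META_COLUMNS = [
    "genome_id", "species", "domain", "group",
    "genome_size_mb", "protein_coding_genes",
]


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read the per-genome metadata TSV; validates schema and vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "species": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        GenomeMetadata(
            genome_id=str(r.genome_id),
            species=str(r.species),
            domain=str(r.domain),
            group=str(r.group),
            genome_size_mb=float(r.genome_size_mb),
            protein_coding_genes=int(r.protein_coding_genes),
        )
        for r in df.itertuples(index=False)
    ]


def write_metadata(records: Iterable[GenomeMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in records], columns=_META_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_bed(loci: Iterable[TRNALocus], path: str | Path) -> None:
    """Export loci as BED6: 0-based half-open, score clamped to [0, 1000]."""
    with open(path, "w") as fh:
        for loc in loci:
            ac = loc.anticodon if loc.anticodon is not UNDETERMINED else "NNN"
            name = f"{loc.genome_id}:{loc.isotype}-{ac}"
            score = int(min(1000, max(0, round(loc.score))))
            fh.write(
                f"{loc.seq_name}\t{loc.begin - 1}\t{loc.end}\t{name}"
                f"\t{score}\t{loc.strand}\n"
            )


def read_fasta(path: str | Path, dna_space: bool = True) -> dict[str, str]:
    """Read FASTA into an id → uppercase sequence mapping.

    With ``dna_space=True`` (default) U is normalized to T.  Duplicate
    ids raise an error listing them.
    """
    seqs: dict[str, str] = {}
    dups: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if dna_space:
            s = s.replace("U", "T")
        if rec.id in seqs:
            dups.append(rec.id)
        seqs[rec.id] = s
    if dups:
        raise ValueError(f"{path}: duplicate FASTA ids: {sorted(set(dups))}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
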