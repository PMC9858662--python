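"""Per-genome tRNA censuses and the cohort quality filter.

A census summarizes one genome's annotated tRNA gene pool: copy numbers
per anticodon and per isotype, the anticodon repertoire (number of
distinct isoacceptors), intron statistics, gene/mature length summaries,
and the set of observed isotype–anticodon combinations.  Pseudogenes
(loci without an assignable anticodon, or flagged as such) are counted
separately and excluded from copy-number and repertoire statistics.

Genomes with fewer than 20 distinct isoacceptors are removed by the
cohort filter — likely incomplete assemblies or poor annotations, since
decoding all 20 amino acids requires at least 20 isoacceptor families.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from statistics import mean, median
from typing import Iterable, Sequence

from . import genetic_code
from .trna_io import TRNALocus, UNDETERMINED

__all__ = ["GenomeCensus", "build_census", "filter_genomes", "unusual_combinations"]

log = logging.getLogger(__name__)


@dataclass
class GenomeCensus:
    """Summary of one genome's tRNA gene pool."""

    genome_id: str
    total_trna: int = 0  # functional loci only
    pseudogene_count: int = 0
    counts_by_anticodon: dict[str, int] = field(default_factory=dict)
    counts_by_isotype: dict[str, int] = field(default_factory=dict)
    counts_by_combination: dict[tuple[str, str], int] = field(default_factory=dict)
    repertoire_size: int = 0
    intron_locus_count: int = 0  # loci (functional + pseudo) with >= 1 intron
    intron_distribution: dict[int, int] = field(default_factory=dict)
    gene_length_mean: float | None = None
    gene_length_median: float | None = None
    mature_length_mean: float | None = None
    mature_length_median: float | None = None

    @property
    def combinations(self) -> set[tuple[str, str]]:
        """Observed (annotated isotype, anticodon) pairs, functional loci."""
        return set(self.counts_by_combination)


def build_census(loci: Sequence[TRNALocus], genome_id: str) -> GenomeCensus:
    """Tally one genome's loci into a :class:`GenomeCensus`.

    * pseudogenes are counted separately and excluded from per-anticodon,
      per-isotype and combination counts;
    * mature length = gene length − summed intron length per locus;
    * length summaries cover functional loci only (pseudogenes yield no
      mature tRNA and follow a different length distribution);
    * ``intron_locus_count`` and ``intron_distribution`` cover all loci.

    An empty locus collection yields an all-zero census, not an error.
    """
    c = GenomeCensus(genome_id=genome_id)
    ac_counts: Counter[str] = Counter()
    iso_counts: Counter[str] = Counter()
    combo_counts: Counter[tuple[str, str]] = Counter()
    intron_dist: Counter[int] = Counter()
    glens: list[int] = []
    mlens: list[int] = []

    for loc in loci:
        if loc.genome_id != genome_id:
            raise ValueError(
                f"locus from {loc.genome_id!r} passed to census of {genome_id!r}"
            )
        intron_dist[loc.n_introns] += 1
        if loc.n_introns > 0:
            c.intron_locus_count += 1
        if loc.is_pseudogene or loc.anticodon is UNDETERMINED:
            c.pseudogene_count += 1
            continue
        c.total_trna += 1
        ac_counts[loc.anticodon] += 1
        iso_counts[loc.isotype] += 1
        combo_counts[(loc.isotype, loc.anticodon)] += 1
        glens.append(loc.gene_length)
        mlens.append(loc.mature_length)

    c.counts_by_anticodon = dict(ac_counts)
    c.counts_by_isotype = dict(iso_counts)
    c.counts_by_combination = dict(combo_counts)
    c.repertoire_size = len(ac_counts)
    c.intron_distribution = dict(intron_dist)
    if glens:
        c.gene_length_mean = mean(glens)
        c.gene_length_median = float(median(glens))
        c.mature_length_mean = mean(mlens)
        c.mature_length_median = float(median(mlens))
    return c


def filter_genomes(
    censuses: Iterable[GenomeCensus],
    min_isoacceptors: int = 20,
    on: str = "isoacceptors",
) -> tuple[list[GenomeCensus], list[GenomeCensus]]:
    """Split censuses into (retained, removed) at the repertoire threshold.

    A genome is retained iff its repertoire (number of distinct
    anticodons; ``on="loci"`` switches to total functional loci) is at
    least ``min_isoacceptors``.  Retained and removed partition the
    input.
    """
    if on not in {"isoacceptors", "loci"}:
        raise ValueError(f"unknown filter criterion {on!r}")
    retained, removed = [], []
    for c in censuses:
        value = c.repertoire_size if on == "isoacceptors" else c.total_trna
        (retained if value >= min_isoacceptors else removed).append(c)
    for c in removed:
        log.info(
            "genome %s removed: %s %d < %d",
            c.genome_id,
            on,
            c.repertoire_size if on == "isoacceptors" else c.total_trna,
            min_isoacceptors,
        )
    return retained, removed


def unusual_combinations(census: GenomeCensus) -> set[tuple[str, str]]:
    """Observed combinations whose annotated isotype conflicts with the code.

    A combination is unusual when the annotated isotype differs from the
    standard-code prediction for its anticodon (pseudogenes are excluded
    upstream).  Suppressor tRNAs (isotype ``Sup``) always count as
    unusual: they decode what the standard code calls a stop.  Initiator
    Met (``iMet``) at anticodon CAT is the standard start and is not
    unusual.
    """
    out: set[tuple[str, str]] = set()
    for iso, ac in census.combinations:
        if iso == "Sup":
            out.add((iso, ac))
            continue
        predicted = genetic_code.predict_isotype(ac).predicted_isotype
        if iso == "iMet" and predicted == "Met":
            continue
        if predicted != iso:
            out.add((iso, ac))
    return out
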