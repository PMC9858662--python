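"""Intraspecific copy-number-variation summaries.

When several complete genomes (strains, isolates, subspecies) exist for
one species, their censuses can be compared to measure how much the tRNA
gene pool varies within the species, and whether that variation reaches
the anticodon repertoire (isoacceptors gained or lost between strains).
Species grouping uses the metadata species string verbatim.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .census import GenomeCensus
from .trna_io import GenomeMetadata

__all__ = ["SpeciesCNVSummary", "species_cnv", "anticodon_presence_matrix"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesCNVSummary:
    species: str
    n_genomes: int
    cn_min: int
    cn_max: int
    cn_mean: float
    cn_sd: float
    fold_range: float  # cn_max / cn_min; NaN (flagged) when cn_min == 0
    repertoire_min: int
    repertoire_max: int
    repertoire_varies: bool


def species_cnv(
    censuses: Sequence[GenomeCensus],
    metadata: Iterable[GenomeMetadata],
    min_genomes: int = 2,
) -> list[SpeciesCNVSummary]:
    """One CNV summary per species with at least ``min_genomes`` genomes.

    Species below the threshold are excluded (and logged).  fold_range
    is cn_max/cn_min; a species whose minimum is 0 gets NaN rather than
    a division error.
    """
    species_of = {m.genome_id: m.species for m in metadata}
    groups: dict[str, list[GenomeCensus]] = {}
    for c in censuses:
        sp = species_of.get(c.genome_id)
        if sp is None:
            log.warning("census %s has no metadata; skipped", c.genome_id)
            continue
        groups.setdefault(sp, []).append(c)

    out = []
    for sp in sorted(groups):
        cs = groups[sp]
        if len(cs) < min_genomes:
            log.info("species %s: only %d genome(s), below %d", sp, len(cs), min_genomes)
            continue
        cns = np.array([c.total_trna for c in cs])
        reps = np.array([c.repertoire_size for c in cs])
        cn_min = int(cns.min())
        if cn_min == 0:
            log.warning("species %s has a zero-CN genome; fold_range undefined", sp)
        out.append(
            SpeciesCNVSummary(
                species=sp,
                n_genomes=len(cs),
                cn_min=cn_min,
                cn_max=int(cns.max()),
                cn_mean=float(cns.mean()),
                cn_sd=float(cns.std(ddof=1)) if len(cs) > 1 else math.nan,
                fold_range=float(cns.max() / cn_min) if cn_min > 0 else math.nan,
                repertoire_min=int(reps.min()),
                repertoire_max=int(reps.max()),
                repertoire_varies=bool(reps.min() < reps.max()),
            )
        )
    return out


def anticodon_presence_matrix(censuses: Sequence[GenomeCensus]) -> pd.DataFrame:
    """Genome × anticodon presence table for one species' strains.

    Boolean cells; column sums give per-anticodon prevalence within the
    species, and non-constant columns identify anticodons gained or lost
    between strains.
    """
    if len(censuses) < 2:
        raise ValueError("presence matrix requires at least 2 genomes")
    anticodons = sorted({ac for c in censuses for ac in c.counts_by_anticodon})
    data = {
        c.genome_id: [c.counts_by_anticodon.get(ac, 0) >= 1 for ac in anticodons]
        for c in censuses
    }
    return pd.DataFrame(data, index=pd.Index(anticodons, name="anticodon")).T
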