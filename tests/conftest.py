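import numpy as np
import pytest

from trnaome.census import GenomeCensus, build_census
from trnaome.trna_io import GenomeMetadata, TRNALocus


@pytest.fixture
def trnascan_text():
    """Hand-written tRNAscan-SE .out fixture: plus strand, minus strand,
    pseudogene, and a two-intron extended-dialect row."""
    return (
        "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\n"
        "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
        "--------\t------\t-----\t----\t----\t-----\t-----\t----\t-----\t----\n"
        "chr1\t1\t1000\t1084\tMet\tCAT\t0\t0\t72.5\n"
        "chr1\t2\t2084\t2000\tLeu\tTAA\t2050\t2062\t60.1\n"
        "chr2\t3\t500\t610\tUndet\tNNN\t0\t0\t28.0\tpseudo\n"
        "chr2\t4\t3000\t3109\tTyr\tGTA\t3030;3060\t3044;3071\t55.0\n"
    )


def make_locus(genome_id="g1", begin=1000, length=85, strand="+", isotype="Met",
               anticodon="CAT", introns=(), score=60.0, pseudo=False):
    return TRNALocus(
        genome_id=genome_id,
        seq_name="chr1",
        begin=begin,
        end=begin + length - 1,
        strand=strand,
        isotype=isotype,
        anticodon=anticodon if not pseudo else None,
        intron_segments=list(introns),
        score=score,
        is_pseudogene=pseudo,
        note="pseudo" if pseudo else "",
    )


def make_census(genome_id, combo_counts, pseudo=0):
    """Census built from per-combination counts via real loci."""
    loci = []
    pos = 1000
    for (iso, ac), k in combo_counts.items():
        for _ in range(k):
            loci.append(make_locus(genome_id, begin=pos, isotype=iso, anticodon=ac))
            pos += 500
    for _ in range(pseudo):
        loci.append(make_locus(genome_id, begin=pos, pseudo=True))
        pos += 500
    return build_census(loci, genome_id)


def make_meta(genome_id, domain, species=None, group="g", size_mb=5.0, pc_genes=3000):
    return GenomeMetadata(
        genome_id=genome_id,
        species=species or f"sp {genome_id}",
        domain=domain,
        group=group,
        genome_size_mb=size_mb,
        protein_coding_genes=pc_genes,
    )


def random_cohort(rng, n_per_domain=(4, 3, 3), combos=None):
    """Small random censuses + metadata for oracle-equivalence checks."""
    if combos is None:
        combos = [("Met", "CAT"), ("Leu", "TAA"), ("Gly", "GCC"),
                  ("Tyr", "GTA"), ("Arg", "ACG"), ("Ile", "GAT")]
    censuses, metas = [], []
    gid = 0
    for domain, n in zip(("Eukarya", "Archaea", "Bacteria"), n_per_domain):
        for _ in range(n):
            counts = {c: int(k) for c, k in zip(combos, rng.integers(0, 4, len(combos))) if k}
            if not counts:
                counts = {combos[0]: 1}
            g = f"g{gid}"
            gid += 1
            censuses.append(make_census(g, counts, pseudo=int(rng.integers(0, 3))))
            metas.append(make_meta(g, domain, size_mb=float(rng.uniform(1, 50))))
    return censuses, metas
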