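#!/usr/bin/env python
"""Build per-genome censuses from the simulated cohort and apply the
20-isoacceptor quality filter.

Reads scratch/cohort/ (produced by 01_simulate_cohort.py), writes
results/census.tsv (one row per retained genome, wide columns for the 64
anticodons) and results/filter_report.tsv, and prints the filter outcome
and per-domain census headlines.
"""

from pathlib import Path

import pandas as pd

from trnaome.census import build_census, filter_genomes
from trnaome.genetic_code import enumerate_anticodons
from trnaome.trna_io import read_metadata, read_trnascan

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def load_censuses():
    metas = read_metadata(COHORT_DIR / "metadata.tsv")
    censuses = [
        build_census(
            read_trnascan(COHORT_DIR / "trnascan" / f"{m.genome_id}.out", m.genome_id),
            m.genome_id,
        )
        for m in metas
    ]
    return censuses, metas


def main() -> None:
    censuses, metas = load_censuses()
    retained, removed = filter_genomes(censuses, min_isoacceptors=20)
    print(
        f"{len(retained)} of {len(censuses)} genomes retained "
        f"({len(removed)} below 20 isoacceptors)"
    )

    anticodons = enumerate_anticodons()
    rows = []
    for c in retained:
        row = {
            "genome_id": c.genome_id,
            "total_trna": c.total_trna,
            "pseudogene_count": c.pseudogene_count,
            "repertoire_size": c.repertoire_size,
            "intron_locus_count": c.intron_locus_count,
            "gene_length_mean": c.gene_length_mean,
            "mature_length_mean": c.mature_length_mean,
        }
        row.update({ac: c.counts_by_anticodon.get(ac, 0) for ac in anticodons})
        rows.append(row)
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "census.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"genome_id": c.genome_id, "repertoire_size": c.repertoire_size,
             "retained": c in retained}
            for c in censuses
        ]
    ).to_csv(RESULTS / "filter_report.tsv", sep="\t", index=False)

    dom = {m.genome_id: m.domain for m in metas}
    df = pd.DataFrame(
        {
            "domain": [dom[c.genome_id] for c in retained],
            "total_trna": [c.total_trna for c in retained],
            "repertoire": [c.repertoire_size for c in retained],
        }
    )
    print(df.groupby("domain").agg(["mean", "median"]).round(1))


if __name__ == "__main__":
    main()
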