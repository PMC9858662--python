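#!/usr/bin/env python
"""Cross-domain comparison: census summaries, pervasiveness, Greek-letter
universality groups, the 70%-pervasiveness Venn overlap, gene densities,
two-group contrasts, and genome-size scaling.

Reads scratch/cohort/, writes the comparison tables under results/ and
prints the group tally, Venn regions and headline scaling slopes.
"""

import sys
from pathlib import Path

import pandas as pd

from trnaome.census import filter_genomes
from trnaome.comparative import (
    classify_groups,
    compare_groups,
    gene_density,
    mean_counts_by,
    pervasiveness,
    scaling_analysis,
    summarize_domain,
    venn_high_pervasiveness,
)

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

load_censuses = import_module("02_census").load_censuses

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    censuses, metas = load_censuses()
    retained, _ = filter_genomes(censuses)
    RESULTS.mkdir(exist_ok=True)

    summary = summarize_domain(retained, metas)
    summary.to_csv(RESULTS / "domain_summary.tsv", sep="\t", index=False)
    print("per-domain tRNA gene count:")
    print(
        summary[summary.metric == "total_trna"]
        .set_index("domain")[["n", "mean", "se", "median", "iqr"]]
        .round(2)
    )

    mean_counts_by(retained, metas, key="anticodon").round(3).to_csv(
        RESULTS / "mean_cn_per_anticodon.tsv", sep="\t"
    )

    pm = pervasiveness(retained, metas)
    pm.fraction.round(4).to_csv(RESULTS / "pervasiveness.tsv", sep="\t")
    pm.mean_cn.round(3).to_csv(RESULTS / "mean_cn_per_combination.tsv", sep="\t")

    labels = classify_groups(pm)
    pd.DataFrame(
        [{"isotype": i, "anticodon": a, "group": g}
         for (i, a), g in sorted(labels.items())]
    ).to_csv(RESULTS / "groups.tsv", sep="\t", index=False)
    tally = pd.Series(labels).value_counts()
    print("\nuniversality groups:", dict(tally))

    venn = venn_high_pervasiveness(pm, threshold=0.70)
    venn_df = pd.DataFrame(
        sorted(
            ({"region": "&".join(sorted(k)), "count": v} for k, v in venn.items()),
            key=lambda r: r["region"],
        )
    )
    venn_df.to_csv(RESULTS / "venn.tsv", sep="\t", index=False)
    print("\n70%-pervasiveness Venn regions:")
    print(venn_df.to_string(index=False))

    dens = gene_density(metas, retained)
    dens.to_csv(RESULTS / "density.tsv", sep="\t", index=False)
    euk = dens[dens.domain == "Eukarya"]["trna_density"]
    bac = dens[dens.domain == "Bacteria"]["trna_density"]
    tests = compare_groups(euk, bac)
    print(
        f"\ntRNA density Eukarya (median {euk.median():.2f}/Mb) vs Bacteria "
        f"(median {bac.median():.2f}/Mb): Welch p = {tests['welch_t'][1]:.2e}, "
        f"U p = {tests['mann_whitney'][1]:.2e}"
    )

    sc = scaling_analysis(metas, retained)
    sc.round(4).to_csv(RESULTS / "scaling.tsv", sep="\t", index=False)
    size_cn = sc[(sc.x == "genome_size_mb") & (sc.y == "total_trna")]
    print("\ntRNA CN vs genome size (log-log slope / Spearman):")
    print(size_cn[["scope", "n", "loglog_slope", "spearman_rho"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
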