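# trnaome

Comparative analysis of tRNA gene repertoires across the three domains of
cellular life, plus classification of tRNA-derived small RNA fragments
(tRFs).

tRNA genes occur as multigene families whose copy number (CN) varies by
orders of magnitude between species, largely tracking genome size, while
the *repertoire* of distinct anticodons (isoacceptors) a genome encodes is
bounded by the 64 possible triplets and varies between ~30 (many bacteria)
and ~60 (vertebrates, land plants). `trnaome` provides the full pipeline
for studying this structure from tRNAscan-SE-style annotation tables:

* **genetic_code** — anticodon/codon algebra in DNA notation: an anticodon
  `a` decodes the codon `revcomp(a)`; the standard code partitions the 64
  anticodons into 20 amino-acid classes plus the 3 stop complements
  (TTA, CTA, TCA), leaving 61 sense codons.
* **trna_io** — readers/writers for tRNAscan-SE tabular `.out` files
  (minus-strand and multi-intron dialects normalized on ingest), FASTA,
  genome metadata TSV, and BED6 export.
* **census** — per-genome summaries: CN per anticodon/isotype, repertoire
  size, intron statistics, gene and mature lengths (mature = gene −
  introns), pseudogenes (loci without an assignable anticodon) counted
  separately; cohort filter removing genomes with < 20 isoacceptors.
* **comparative** — per-domain statistics (mean, SD, SE, median, IQR),
  the **pervasiveness matrix** P[c, d] = fraction of domain-d genomes
  carrying combination c = (isotype, anticodon), Greek-letter universality
  groups (α: > 70% in all domains; β: eukaryotes+archaea; γ: prokaryotes;
  δ: eukaryotes only; ε: rare everywhere), 70%-pervasiveness Venn
  overlaps, per-Mb gene densities, Welch t / Mann–Whitney U contrasts,
  and log–log scaling of CN with genome size.
* **cnv** — intraspecific copy-number variation across strains of one
  species (fold range, repertoire gains/losses, presence matrices).
* **trf** — exact-match classification of small RNA fragments into tRF-5
  (5′ of the mature tRNA), tRF-3 (3′ end, CCA-aware) and tRF-1
  (3′ trailer of the primary transcript), with redundancy, length-spectrum
  and CN-correlation statistics.
* **simulate / profiles** — a synthetic cohort generator with per-domain
  profiles (genome-size ranges, power-law CN scaling, pervasiveness
  vectors, intron probabilities, length distributions, pseudogene rates)
  so every stage is testable without database downloads.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # 420 genomes -> scratch/cohort/
python analysis/02_census.py
python analysis/03_domain_comparison.py
```

prints, among other tables:

```
per-domain tRNA gene count:
            n    mean      se  median     iqr
domain
Archaea    60   49.78    1.30    44.5   12.25
Bacteria  300   72.25    1.94    62.5   45.25
Eukarya    60  767.98  174.65   212.5  939.50

universality groups: {'alpha': 27, 'delta': 9, 'beta': 8, 'gamma': 8, 'epsilon': 8, 'other': 3}

tRNA CN vs genome size (log-log slope / Spearman):
   scope   n  loglog_slope  spearman_rho
     all 420         0.308         0.776
 Archaea  60         0.309         0.881
Bacteria 300         0.411         0.866
 Eukarya  60         0.632         0.942
```

i.e. eukaryote genomes in this cohort carry an order of magnitude more
tRNA loci than prokaryotes with a much wider spread; 27 anticodon–amino-
acid combinations are near-universal (α-group) while 8 are shared only by
eukaryotes and archaea (β) and 8 only by prokaryotes (γ); and tRNA CN
rises with genome size in every domain (Spearman 0.78–0.94 on this
cohort). `analysis/04_intraspecific_cnv.py` shows strain cohorts varying
more than two-fold in CN and a 17-strain cohort in which one strain has
one fewer isoacceptor; `analysis/05_trf_analysis.py` reproduces the tRF
structure (total tRFs track tRNA CN, rho ≈ 0.99; unique tRFs do not,
rho ≈ 0.18 n.s.; the highest-CN species' pools are > 98% redundant).

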