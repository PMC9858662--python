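# Methods

## Conventions

All triplet algebra is done in DNA notation (T, not U), 5′→3′; RNA-space
input (mature tRNA sequences, fragment FASTA) is mapped U→T on ingest and
a display-only transform back to RNA is provided. An anticodon decodes
the codon equal to its reverse complement; isotypes are predicted from
the standard genetic code (NCBI translation table 1, shipped as a
versioned asset in `trnaome/data/codon_table.tsv`). Non-standard codes
are out of scope: the three standard stop complements TTA/CTA/TCA predict
STOP, and annotation isotypes (Sec at TCA, Sup suppressors, iMet) always
override the prediction in the census — prediction is used only to flag
unusual isotype–anticodon combinations (Sup always counts as unusual;
iMet/CAT never does).

Coordinates are normalized once at parse time to 1-based inclusive
`begin ≤ end` with an explicit strand (tRNAscan-SE conveys minus-strand
loci as begin > end); BED export converts to 0-based half-open. Gene
length = end − begin + 1; mature length = gene length − summed intron
length. The post-transcriptional CCA tail is *not* added to mature
lengths (lengths are encoded lengths); tRF-3 matching, where CCA
matters, tries both forms and tags matches that needed the appended CCA.

A locus is a pseudogene iff its anticodon is undetermined (`NNN`/`???`)
or its note column mentions "pseudo". Pseudogenes are excluded from
copy-number, repertoire, combination and length statistics but counted
alongside (they follow a different, longer length distribution and yield
no mature tRNA); intron counts cover all loci.

## Cohort filter

Genomes with fewer than 20 *distinct anticodons* are removed before
cross-genome analysis: decoding 20 amino acids requires at least 20
isoacceptor families, so a smaller repertoire indicates an incomplete
assembly or annotation. "Fewer than 20 isoacceptors" is read as distinct
anticodons, not loci — isoacceptor denotes anticodon identity — but the
alternative reading is exposed (`filter_genomes(..., on="loci")`,
CLI `--filter-on`).

## Pervasiveness and universality groups

For combination c and domain d, pervasiveness P[c, d] is the fraction of
retained domain-d genomes with ≥ 1 functional copy of c; mean CN per
combination averages over all genomes of the domain, zeros included.
With high = 0.70 and low = 0.30 (both configurable), the Greek groups
are: α (all domains > high), β (EUK, ARC > high; BAC ≤ low), γ (ARC,
BAC > high; EUK ≤ low), δ (EUK > high; ARC, BAC ≤ low), ε (all ≤ low),
and "other" for every remaining mixed pattern (e.g. a combination shared
by eukaryotes and bacteria but rare in archaea fits none of the five).
The low threshold quantifies "avoided/rare", which is otherwise
qualitative; 0.30 leaves an unambiguous gap below the 0.70 "frequent"
cutoff. Labels are exhaustive and mutually exclusive by construction.
Venn overlaps take, per domain, the set of combinations with P > 0.70
and report the seven region counts, which sum to the union.

## Two-group tests

`compare_groups` reports Welch's two-sample t (Satterthwaite degrees of
freedom; an explicit error, not NaN, when both samples are constant) and
the Mann–Whitney U, both two-sided, delegated to scipy. The U p-value
uses exact enumeration when both samples have n ≤ 20 and no ties, and
the tie-corrected normal approximation with continuity correction
otherwise. The conventional 0.05 significance threshold is a reporting
convention, not enforced; p-values are emitted raw (no multiplicity
correction; a Benjamini–Hochberg helper is available to users via
pandas/scipy if needed). Quantiles (median, IQR) use linear
interpolation throughout, and SD/SE on single observations are reported
missing, never zero.

## Scaling analysis

For each pair among {genome size, tRNA CN, protein-coding genes,
repertoire size, pseudogene count}, overall and per domain: Spearman
rank correlation on raw values and an OLS slope of log10 y on log10 x
restricted to strictly positive values. Both are reported because
neither alone captures monotone association and power-law form. Pairs
with < 3 points are skipped; a constant margin reports rho = 0 (no rank
signal) and inherits the 0 slope from the fit.

## Synthetic cohorts: what the generator emulates

Each domain profile fixes:

* **Genome size** — log-uniform over Archaea 1–6 Mb, Bacteria 0.5–10 Mb,
  Eukarya 10 Mb–100 Gb.
* **Copy number** — CN = a·size_mb^b·exp(N(0, σ)), with Eukarya
  (a = 0.2, b = 1.0, σ = 0.5), Archaea (30, 0.5, 0.05), Bacteria
  (40, 0.5, 0.25). The exponents and intercepts are design choices, not
  estimates: b = 1 for eukaryotes vs b = 0.5 for prokaryotes reproduces
  the qualitative contrast that eukaryotic tRNA CN keeps expanding with
  genome size while prokaryotic expansion is damped, and the intercepts
  put median CN near 200 (eukaryotes), 57 (bacteria) and 47 (archaea).
  CN is floored at max(20, drawn repertoire); a draw below the floor is
  resampled up to 10 times and then floored with a logged warning —
  never silently truncated. For archaea, whose CN barely exceeds their
  repertoire, the floor binds often; that is a property of the regime,
  not an artifact.
* **Repertoire** — each combination enters the genome by an independent
  Bernoulli draw from the domain's pervasiveness vector; every included
  combination receives ≥ 1 copy and the surplus CN is multinomial with
  weights p² + 0.05 (pervasive combinations are preferentially
  amplified), Met/CAT weighted 4× (the universally amplified initiator
  decoder). The default vectors are built deterministically from the
  standard code: a 27-combination near-universal core (one anticodon per
  amino acid, two for amino acids with ≥ 4 anticodons, Ile excluded —
  mirroring an α-group covering 19 of 20 amino acids), fixed
  domain-split special cases (Ile/GAT prokaryotic vs Ile/AAT+TAT
  eukaryotic; Arg/ACG vs Arg/GCG; Sup/TTA at 21.65% of eukaryotes and
  0.79% of bacteria; rare Sec/TCA), and the remaining anticodons cycled
  through β/γ/δ/ε-like probability patterns. Expected repertoires are
  ≈ 45 (Eukarya), 42 (Archaea), 37 (Bacteria).
* **Introns** — per-locus Bernoulli with p = 0.2230 (Eukarya), 0.1899
  (Archaea), 0.0011 (Bacteria); single intron per locus by default
  (the parser accepts multi-intron records), Gaussian lengths (means
  18/16/12 nt), placed downstream of the anticodon arm.
* **Lengths** — gene lengths Gaussian with means 84.70 (Eukarya), 83.10
  (Archaea), 77.60 bp (Bacteria; tight sd 2.5 vs 5 elsewhere), floored
  at 62 bp; pseudogenes run 15 bp longer on average.
* **Pseudogenes** — emitted at rates 0.03/0.005/0.005 of CN
  (eukaryotes accumulate more), with undetermined anticodons and a
  "pseudo" note.
* **Protein-coding genes** — a saturating Michaelis–Menten curve
  cap·size/(K + size), eukaryote cap 35,000 (K = 30 Mb), so gene counts
  plateau in giant genomes while tRNA CN keeps growing.

One RNG stream per genome, derived from (master seed, genome index),
makes cohorts byte-reproducible and order-independent. The species
cohort variant rescales a base genome's per-combination counts by a
per-strain lognormal factor (cnv_sd = 0 ⇒ identical strains) and can
force or randomize the loss of one anticodon per strain. The tRF pool
generator cuts exact prefixes/suffixes (13–38 nt) from random
mature+trailer models with a Poisson-distributed duplication factor and
writes truth labels.

What the generator does **not** emulate: real tRNA sequences or
secondary structure (scores are placeholders), codon-usage coupling,
phylogenetic autocorrelation between genomes, assembly artifacts, and
within-domain taxonomic structure beyond a group label. Passing
recovery tests therefore demonstrates that the pipeline measures what
the generative model encodes — not that real databases satisfy that
model.

## tRF classification

Exact end-matching only (fragments in these databases derive from exact
genomic sequence): tRF-5 ⇔ prefix of a mature sequence, tRF-3 ⇔ suffix
of mature or mature+CCA (tagged when CCA was required), tRF-1 ⇔ prefix
of a trailer. Sources accumulate over all matching models of the
assigned class; multi-class matches resolve by the fixed priority
tRF-5 > tRF-3 > tRF-1 and are flagged ambiguous so totals are conserved.
Fragments under 13 nt (the observed floor) are rejected with a reason.
Redundancy and length spectra are computed over distinct sequences.

## Problem sizes and tolerances

The recovery benchmarks in `scripts/acceptance.py` use 500 eukaryote
genomes with sizes narrowed to 0.5–2 Gb — keeping the stock CN model at
~200 loci per genome, ~10⁵ loci pooled — plus 500 archaea (~25k loci)
and 900 bacteria (~55k loci, also serving the gene-length recovery at
well over the 10⁴-locus floor). At these sizes the binomial standard
error on an intron fraction is ≤ 0.3 percentage points, comfortably
inside the ±1.0 (±0.05 for bacteria) acceptance bands, and the standard
error on the bacterial mean gene length is ~0.01 bp against a ±0.5 bp
band. Oracle-equivalence tests run 100+ randomized small fixtures
against independent brute-force implementations; the statistical tests
are checked against closed-form/enumeration references to 1e-10;
noiseless power-law recovery is asserted to 1e-6.

## Known limitations

* Single genetic code; organisms with reassigned codons would need a
  different table asset.
* Pseudogene identity is operational (no assignable anticodon or an
  explicit note); databases using other flags need a mapping step.
* The pervasiveness vector treats combinations independently, so
  co-occurrence structure between anticodons is absent from synthetic
  cohorts.
* tRF matching has no mismatch/indel tolerance and exact end positions;
  `--end-slack`-style trimming tolerance is not implemented.
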