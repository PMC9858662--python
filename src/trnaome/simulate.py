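"""Synthetic cohort generator.

Emits tRNAscan-SE-format annotation files (one per genome), a metadata
TSV and a JSON manifest, with the statistical structure the comparative
analyses assume: domain-specific genome-size ranges, power-law tRNA copy
number scaling with genome size, domain-specific anticodon pervasiveness
profiles, per-locus Bernoulli introns, Gaussian gene-length
distributions, pseudogene loci with undetermined anticodons, and
saturating protein-coding gene counts.  A species-cohort variant
emulates intraspecific copy-number variation, and a tRF-pool generator
cuts labelled fragments from synthetic tRNA models.

Reproducibility: one RNG stream per genome, derived from (master seed,
genome index), so a cohort is byte-identical for a fixed spec + seed and
stable under parallel generation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .profiles import DomainProfile, default_profiles
from .trna_io import (
    GenomeMetadata,
    TRNALocus,
    write_metadata,
    write_trnascan,
)
from .trf import MAX_TRF_LENGTH, MIN_TRF_LENGTH, TRNAModel

__all__ = [
    "CohortSpec",
    "TRFPoolProfile",
    "generate_genome",
    "generate_cohort",
    "generate_species_cohort",
    "generate_trna_models",
    "generate_trf_pool",
]

log = logging.getLogger(__name__)

_MIN_CN = 20  # floor on functional loci per genome
_MIN_GENE_LEN = 62  # shortest credible tRNA gene
_CN_RESAMPLE_TRIES = 10


@dataclass(frozen=True)
class CohortSpec:
    """How many genomes to draw per domain, and with which master seed."""

    n_per_domain: Mapping[str, int]
    seed: int

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_domain.values()):
            raise ValueError("genome counts must be >= 0")


def _sample_cn(profile: DomainProfile, size_mb: float, n_combos: int,
               rng: np.random.Generator) -> int:
    a, b, sd = profile.cn_scaling
    floor = max(_MIN_CN, n_combos)
    for _ in range(_CN_RESAMPLE_TRIES):
        cn = int(round(a * size_mb**b * math.exp(rng.normal(0.0, sd))))
        if cn >= floor:
            return cn
    log.warning(
        "%s: CN below floor %d after %d draws; using floor",
        profile.domain, floor, _CN_RESAMPLE_TRIES,
    )
    return floor


def generate_genome(
    genome_id: str,
    profile: DomainProfile,
    rng: np.random.Generator,
    species: str | None = None,
    combo_counts: Mapping[tuple[str, str], int] | None = None,
) -> tuple[list[TRNALocus], GenomeMetadata]:
    """Draw one genome: its metadata and a list of normalized loci.

    Unless ``combo_counts`` pins the per-combination copy numbers (used
    by the species-cohort generator), the genome's combination set is a
    Bernoulli draw from the profile's pervasiveness vector and copy
    numbers are multinomial over included combinations, weighted towards
    pervasive ones (with an extra boost for the initiator-decoding
    Met/CAT, the most amplified tRNA gene in all domains).
    """
    lo, hi = profile.genome_size_range_mb
    size_mb = math.exp(rng.uniform(math.log(lo), math.log(hi)))

    if combo_counts is None:
        combos = sorted(profile.pervasiveness)
        probs = np.array([profile.pervasiveness[c] for c in combos])
        included = [c for c, p in zip(combos, probs) if rng.random() < p]
        if not included:  # vanishingly unlikely; keep the genome usable
            included = combos
        cn = _sample_cn(profile, size_mb, len(included), rng)
        weights = np.array(
            [profile.pervasiveness[c] ** 2 + 0.05 for c in included]
        )
        for i, c in enumerate(included):
            if c == ("Met", "CAT"):
                weights[i] *= 4.0  # universally amplified initiator decoder
        # every included combination is present (>= 1 copy); the surplus
        # CN is spread with a skew favoring pervasive combinations
        counts = 1 + rng.multinomial(cn - len(included), weights / weights.sum())
        combo_counts = {c: int(k) for c, k in zip(included, counts)}
    else:
        combo_counts = {c: int(k) for c, k in combo_counts.items() if k > 0}
        cn = sum(combo_counts.values())

    n_pseudo = int(rng.binomial(cn, profile.pseudogene_rate)) if cn else 0

    # per-locus attribute draws, vectorized over the genome
    n_total = cn + n_pseudo
    glen_mean, glen_sd = profile.gene_length
    ilen_mean, ilen_sd = profile.intron_length
    lengths = np.maximum(
        _MIN_GENE_LEN, np.round(rng.normal(glen_mean, glen_sd, n_total))
    ).astype(int)
    lengths[cn:] += int(round(profile.pseudogene_extra_bp))
    has_intron = rng.random(n_total) < profile.intron_prob
    intron_lens = np.maximum(8, np.round(rng.normal(ilen_mean, ilen_sd, n_total))).astype(int)
    gaps = rng.integers(200, 2000, n_total)
    minus = rng.random(n_total) < 0.5
    scores = np.round(rng.uniform(30.0, 90.0, n_total), 1)

    flat: list[tuple[str, str | None]] = []
    for (iso, ac), k in sorted(combo_counts.items()):
        flat.extend([(iso, ac)] * k)
    flat.extend([("Undet", None)] * n_pseudo)

    loci: list[TRNALocus] = []
    cursor = 1000
    for i, (iso, ac) in enumerate(flat):
        begin = cursor + int(gaps[i])
        L = int(lengths[i])
        end = begin + L - 1
        cursor = end
        introns: list[tuple[int, int]] = []
        if has_intron[i]:
            ilen = min(int(intron_lens[i]), L - 55)  # keep exonic arms intact
            if ilen >= 8:
                istart = begin + 30  # after the anticodon arm, canonical site
                introns = [(istart, istart + ilen - 1)]
        is_pseudo = ac is None
        loci.append(
            TRNALocus(
                genome_id=genome_id,
                seq_name="chr1",
                begin=begin,
                end=end,
                strand="-" if minus[i] else "+",
                isotype=iso,
                anticodon=ac,
                intron_segments=introns,
                score=float(scores[i]) if not is_pseudo else float(scores[i]) / 2,
                is_pseudogene=is_pseudo,
                note="pseudo" if is_pseudo else "",
            )
        )

    cap, k_mb = profile.protein_gene_model
    pc = cap * size_mb / (k_mb + size_mb)
    pc = int(round(pc * math.exp(rng.normal(0.0, profile.protein_gene_sd))))
    meta = GenomeMetadata(
        genome_id=genome_id,
        species=species if species is not None else f"Synthetica {genome_id}",
        domain=profile.domain,
        group=profile.groups[int(rng.integers(len(profile.groups)))],
        genome_size_mb=round(size_mb, 4),
        protein_coding_genes=max(0, pc),
    )
    return loci, meta


def _genome_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    profiles: Mapping[str, DomainProfile] | None = None,
) -> dict:
    """Write a full synthetic cohort to ``out_dir``.

    Layout: one ``<genome_id>.out`` annotation file per genome under
    ``out_dir/trnascan/``, ``metadata.tsv``, and ``manifest.json``
    recording the seed and per-genome sampled parameters.  Returns the
    manifest as a dict.
    """
    profiles = profiles if profiles is not None else default_profiles()
    out_dir = Path(out_dir)
    scan_dir = out_dir / "trnascan"
    scan_dir.mkdir(parents=True, exist_ok=True)

    metas: list[GenomeMetadata] = []
    manifest_genomes = []
    index = 0
    for domain in sorted(spec.n_per_domain):
        n = spec.n_per_domain[domain]
        profile = profiles[domain]
        for j in range(n):
            gid = f"{domain[:3].upper()}{j:04d}"
            rng = _genome_rng(spec.seed, index)
            loci, meta = generate_genome(gid, profile, rng)
            write_trnascan(loci, scan_dir / f"{gid}.out")
            metas.append(meta)
            manifest_genomes.append(
                {
                    "genome_id": gid,
                    "domain": domain,
                    "rng_index": index,
                    "n_loci": len(loci),
                    "n_functional": sum(1 for l in loci if not l.is_pseudogene),
                    "genome_size_mb": meta.genome_size_mb,
                }
            )
            index += 1

    write_metadata(metas, out_dir / "metadata.tsv")
    manifest = {
        "seed": spec.seed,
        "n_per_domain": dict(spec.n_per_domain),
        "genomes": manifest_genomes,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def generate_species_cohort(
    base_profile: DomainProfile,
    species: str,
    n_strains: int,
    seed: int,
    cnv_sd: float = 0.2,
    repertoire_loss_prob: float = 0.0,
    n_forced_losses: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[TRNALocus]], list[GenomeMetadata]]:
    """Generate ``n_strains`` genomes of one species with jittered CN.

    A base genome is drawn from the profile; each strain rescales every
    combination count by a shared lognormal factor exp(N(0, cnv_sd))
    (so ``cnv_sd = 0`` reproduces the base counts exactly).  With
    probability ``repertoire_loss_prob`` — or in exactly
    ``n_forced_losses`` randomly chosen strains — a strain loses all
    copies of one random anticodon, shrinking its repertoire by one.
    """
    if n_strains < 2:
        raise ValueError("a species cohort needs at least 2 strains")
    rng = np.random.default_rng([seed, 0])
    base_loci, base_meta = generate_genome(
        f"{species}_base", base_profile, rng, species=species
    )
    base_counts: dict[tuple[str, str], int] = {}
    for loc in base_loci:
        if not loc.is_pseudogene:
            base_counts[(loc.isotype, loc.anticodon)] = (
                base_counts.get((loc.isotype, loc.anticodon), 0) + 1
            )

    if n_forced_losses is not None:
        if not 0 <= n_forced_losses <= n_strains:
            raise ValueError("n_forced_losses out of range")
        lose = np.zeros(n_strains, dtype=bool)
        lose[rng.choice(n_strains, size=n_forced_losses, replace=False)] = True
    else:
        lose = rng.random(n_strains) < repertoire_loss_prob

    cohort: dict[str, list[TRNALocus]] = {}
    metas: list[GenomeMetadata] = []
    for s in range(n_strains):
        srng = np.random.default_rng([seed, 1 + s])
        factor = math.exp(srng.normal(0.0, cnv_sd)) if cnv_sd > 0 else 1.0
        counts = {
            combo: max(1, int(round(k * factor))) if factor != 1.0 else k
            for combo, k in base_counts.items()
        }
        if lose[s]:
            dropped = sorted(counts)[int(srng.integers(len(counts)))]
            del counts[dropped]
            log.info("strain %d of %s loses %s", s, species, dropped)
        gid = f"{species.replace(' ', '_')}_s{s:02d}"
        loci, meta = generate_genome(
            gid, base_profile, srng, species=species, combo_counts=counts
        )
        cohort[gid] = loci
        metas.append(meta)

    if out_dir is not None:
        out_dir = Path(out_dir)
        scan_dir = out_dir / "trnascan"
        scan_dir.mkdir(parents=True, exist_ok=True)
        for gid, loci in cohort.items():
            write_trnascan(loci, scan_dir / f"{gid}.out")
        write_metadata(metas, out_dir / "metadata.tsv")
    return cohort, metas


# --------------------------------------------------------------------------
# tRF pools


@dataclass(frozen=True)
class TRFPoolProfile:
    """Shape of a synthetic tRF pool.

    ``n_distinct_per_type`` distinct fragments are cut per class;
    ``duplication_factor`` is the mean number of copies per distinct
    fragment (1.0 → every fragment unique); lengths are uniform over
    ``length_range`` clipped to the available sequence.
    """

    n_distinct_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"tRF-1": 20, "tRF-3": 30, "tRF-5": 25}
    )
    duplication_factor: float = 1.0
    length_range: tuple[int, int] = (MIN_TRF_LENGTH, MAX_TRF_LENGTH)

    def __post_init__(self) -> None:
        if self.duplication_factor < 1.0:
            raise ValueError("duplication_factor must be >= 1")
        lo, hi = self.length_range
        if not MIN_TRF_LENGTH <= lo <= hi <= MAX_TRF_LENGTH:
            raise ValueError(
                f"length_range must sit within [{MIN_TRF_LENGTH}, {MAX_TRF_LENGTH}]"
            )


def generate_trna_models(
    n: int, rng: np.random.Generator,
    mature_length: tuple[int, int] = (70, 90),
    trailer_length: tuple[int, int] = (20, 40),
) -> list[TRNAModel]:
    """Random mature+trailer tRNA models (uniform base composition)."""
    bases = np.array(list("ACGT"))
    models = []
    for i in range(n):
        mlen = int(rng.integers(mature_length[0], mature_length[1] + 1))
        tlen = int(rng.integers(trailer_length[0], trailer_length[1] + 1))
        mature = "".join(bases[rng.integers(0, 4, mlen)])
        trailer = "".join(bases[rng.integers(0, 4, tlen)])
        models.append(TRNAModel(f"trna{i:04d}", mature, trailer))
    return models


def generate_trf_pool(
    models: Sequence[TRNAModel],
    profile: TRFPoolProfile,
    seed: int,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Cut a labelled fragment pool from tRNA models.

    Returns ``(fragments, truth)`` where fragments is a list of
    (fragment_id, sequence) — duplicates included, shuffled — and truth
    is one record per distinct fragment: id, sequence, true type, source
    model and copy count.  Fragment FASTA plus a truth-label TSV can be
    written from these by the caller.
    """
    rng = np.random.default_rng(seed)
    lo, hi = profile.length_range
    truth: list[dict] = []
    fragments: list[tuple[str, str]] = []
    fid = 0
    for trf_type in sorted(profile.n_distinct_per_type):
        n_distinct = profile.n_distinct_per_type[trf_type]
        emitted: set[str] = set()
        attempts = 0
        while len(emitted) < n_distinct and attempts < n_distinct * 50:
            attempts += 1
            m = models[int(rng.integers(len(models)))]
            if trf_type == "tRF-1":
                source, take_from = m.trailer_seq, "start"
            elif trf_type == "tRF-5":
                source, take_from = m.mature_seq, "start"
            else:
                source, take_from = m.mature_seq + "CCA", "end"
            max_len = min(hi, len(source))
            if max_len < lo:
                continue
            L = int(rng.integers(lo, max_len + 1))
            frag = source[:L] if take_from == "start" else source[-L:]
            if frag in emitted:
                continue
            emitted.add(frag)
            copies = 1 + int(rng.poisson(profile.duplication_factor - 1.0))
            name = f"frag{fid:05d}"
            fid += 1
            truth.append(
                {
                    "fragment_id": name,
                    "sequence": frag,
                    "true_type": trf_type,
                    "source_trna": m.trna_id,
                    "copies": copies,
                }
            )
            for c in range(copies):
                fragments.append((f"{name}.{c}", frag))
        if len(emitted) < n_distinct:
            log.warning(
                "%s: only %d/%d distinct fragments could be cut",
                trf_type, len(emitted), n_distinct,
            )
    order = rng.permutation(len(fragments))
    return [fragments[i] for i in order], truth
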