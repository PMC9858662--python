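"""Default generator profiles for the three domains of cellular life.

A :class:`DomainProfile` bundles everything the cohort generator needs
for one domain: the genome-size range (sampled log-uniformly), the
power-law copy-number scaling CN = a · size_mb^b · lognormal(sd), the
per-combination pervasiveness vector (inclusion probabilities for
isotype–anticodon combinations), intron frequency, gene- and
intron-length distributions, the pseudogene rate, and a saturating
(Michaelis–Menten-shaped) protein-coding gene model.

Domain anchors:

* genome-size ranges — Archaea ~1–6 Mb, Bacteria ~0.5–10 Mb, Eukarya
  ~10 Mb–100 Gb;
* per-locus intron probabilities — Eukarya 0.2230, Archaea 0.1899,
  Bacteria 0.0011;
* gene-length means — Bacteria 77.60 bp (tight, sd 2.5), Archaea
  83.10 bp, Eukarya 84.70 bp (sd 5);
* eukaryote protein-coding gene cap ≈ 35,000 per haploid genome.

The CN-scaling exponents (Eukarya b = 1.0, prokaryotes b = 0.5) and the
pervasiveness vector are synthetic design choices, not estimates; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import genetic_code

__all__ = ["DomainProfile", "default_pervasiveness", "default_profiles"]


@dataclass(frozen=True)
class DomainProfile:
    domain: str
    genome_size_range_mb: tuple[float, float]
    cn_scaling: tuple[float, float, float]  # (a, b, lognormal sd in ln-space)
    pervasiveness: dict[tuple[str, str], float]  # (isotype, anticodon) -> P(include)
    intron_prob: float
    gene_length: tuple[float, float]  # (mean, sd) bp
    intron_length: tuple[float, float] = (15.0, 4.0)  # (mean, sd) nt
    pseudogene_rate: float = 0.01
    pseudogene_extra_bp: float = 15.0  # pseudogenes run longer than functional loci
    protein_gene_model: tuple[float, float] = (20000.0, 18.0)  # (cap, K_mb)
    protein_gene_sd: float = 0.10  # lognormal sd on protein-coding counts
    groups: tuple[str, ...] = ("unassigned",)

    def __post_init__(self) -> None:
        lo, hi = self.genome_size_range_mb
        if not (0 < lo < hi):
            raise ValueError("genome size range must satisfy 0 < lo < hi")
        a, b, sd = self.cn_scaling
        if a <= 0 or b < 0 or sd < 0:
            raise ValueError("cn_scaling requires a > 0, b >= 0, sd >= 0")
        if not 0 <= self.intron_prob <= 1:
            raise ValueError("intron_prob must be a probability")
        if not 0 <= self.pseudogene_rate <= 1:
            raise ValueError("pseudogene_rate must be a probability")
        for p in self.pervasiveness.values():
            if not 0 <= p <= 1:
                raise ValueError("pervasiveness entries must be probabilities")
        if min(self.gene_length[0], self.intron_length[0]) <= 0:
            raise ValueError("length parameters must be positive")

    def with_overrides(self, **kwargs) -> "DomainProfile":
        return replace(self, **kwargs)


# Combinations the generator treats specially, with per-domain inclusion
# probabilities (Eukarya, Archaea, Bacteria).  These mirror the known
# taxon-specific decoding choices: Ile/GAT is prokaryotic, Ile/AAT and
# Ile/TAT eukaryotic; Arg/ACG is shared by eukaryotes and bacteria but
# rare in archaea, Arg/GCG the reverse; the TTA suppressor occurs in
# 21.65% of eukaryotes and 0.79% of bacteria; Sec/TCA is rare everywhere.
_SPECIAL = {
    ("Ile", "GAT"): (0.3148, 1.00, 0.9796),
    ("Ile", "AAT"): (0.9785, 0.01, 0.0141),
    ("Ile", "TAT"): (0.9570, 0.01, 0.0141),
    ("Arg", "ACG"): (0.90, 0.10, 0.90),
    ("Arg", "GCG"): (0.10, 0.90, 0.10),
    ("Sup", "TTA"): (0.2165, 0.0, 0.0079),
    ("Sec", "TCA"): (0.15, 0.05, 0.10),
}

# Rotating probability patterns for non-core, non-special combinations,
# emulating the β/γ/δ/ε universality classes (EUK, ARC, BAC).
_PATTERNS = (
    (0.85, 0.80, 0.05),  # β-like: eukaryotes + archaea
    (0.08, 0.80, 0.85),  # γ-like: prokaryotes
    (0.85, 0.10, 0.05),  # δ-like: eukaryotes only
    (0.25, 0.15, 0.25),  # ε-like: rare everywhere
)

_CORE_P = (0.97, 0.97, 0.97)


def default_pervasiveness() -> dict[str, dict[tuple[str, str], float]]:
    """Deterministic per-domain pervasiveness vectors over the standard code.

    Construction: each sense anticodon is paired with its standard-code
    isotype.  A core of near-universal combinations (first anticodon per
    amino acid, plus a second one for amino acids with ≥ 4 anticodons,
    Ile excluded) gets p = 0.97 in every domain — mirroring a ~26-strong
    α-group covering 19 of the 20 standard amino acids.  The named
    special cases above are fixed; every remaining combination cycles
    deterministically through β/γ/δ/ε-like patterns.
    """
    by_aa: dict[str, list[str]] = {}
    for ac in genetic_code.enumerate_anticodons():
        iso = genetic_code.predict_isotype(ac).predicted_isotype
        if iso == genetic_code.STOP:
            continue
        by_aa.setdefault(iso, []).append(ac)

    special_acs = {ac for _, ac in _SPECIAL}
    core: list[tuple[str, str]] = []
    for iso in sorted(by_aa):
        if iso == "Ile":
            continue  # Ile decoding is domain-split; no universal anticodon
        candidates = [ac for ac in sorted(by_aa[iso]) if ac not in special_acs]
        take = 2 if len(by_aa[iso]) >= 4 else 1
        core.extend((iso, ac) for ac in candidates[:take])

    euk: dict[tuple[str, str], float] = {}
    arc: dict[tuple[str, str], float] = {}
    bac: dict[tuple[str, str], float] = {}
    for combo, (pe, pa, pb) in _SPECIAL.items():
        euk[combo], arc[combo], bac[combo] = pe, pa, pb
    for combo in core:
        euk[combo], arc[combo], bac[combo] = _CORE_P

    i = 0
    for iso in sorted(by_aa):
        for ac in sorted(by_aa[iso]):
            combo = (iso, ac)
            if combo in euk or ac in special_acs:
                continue
            pe, pa, pb = _PATTERNS[i % len(_PATTERNS)]
            euk[combo], arc[combo], bac[combo] = pe, pa, pb
            i += 1
    return {"Eukarya": euk, "Archaea": arc, "Bacteria": bac}


def default_profiles() -> dict[str, DomainProfile]:
    """The three stock domain profiles used throughout the analyses."""
    perv = default_pervasiveness()
    return {
        "Eukarya": DomainProfile(
            domain="Eukarya",
            genome_size_range_mb=(10.0, 100_000.0),
            cn_scaling=(0.2, 1.0, 0.5),
            pervasiveness=perv["Eukarya"],
            intron_prob=0.2230,
            gene_length=(84.70, 5.0),
            intron_length=(18.0, 5.0),
            pseudogene_rate=0.03,
            protein_gene_model=(35_000.0, 30.0),
            groups=("vertebrates", "invertebrates", "land plants", "Fungi", "Protozoa"),
        ),
        "Archaea": DomainProfile(
            domain="Archaea",
            genome_size_range_mb=(1.0, 6.0),
            cn_scaling=(30.0, 0.5, 0.05),
            pervasiveness=perv["Archaea"],
            intron_prob=0.1899,
            gene_length=(83.10, 5.0),
            intron_length=(16.0, 5.0),
            pseudogene_rate=0.005,
            protein_gene_model=(15_000.0, 13.0),
            groups=("Euryarchaeota", "Thaumarchaeota", "Crenarchaeota"),
        ),
        "Bacteria": DomainProfile(
            domain="Bacteria",
            genome_size_range_mb=(0.5, 10.0),
            cn_scaling=(40.0, 0.5, 0.25),
            pervasiveness=perv["Bacteria"],
            intron_prob=0.0011,
            gene_length=(77.60, 2.5),
            intron_length=(12.0, 3.0),
            pseudogene_rate=0.005,
            protein_gene_model=(20_000.0, 18.0),
            groups=("Proteobacteria", "Firmicutes", "Actinobacteria",
                    "Chloroflexi", "Tenericutes", "Fusobacteria"),
        ),
    }
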