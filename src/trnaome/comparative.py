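"""Domain- and taxon-level comparative statistics.

Covers the cross-genome aggregation layer: per-domain summary statistics
of censuses, the pervasiveness matrix of isotype–anticodon combinations
(fraction of genomes in a domain carrying at least one functional copy),
the Greek-letter universality classification of combinations, Venn
overlaps of high-pervasiveness sets, per-Mb gene densities, two-group
location tests (Welch t, Mann–Whitney U), and genome-size scaling
analyses (Spearman correlations and log10–log10 OLS slopes).

Quantiles use the linear-interpolation convention (numpy default), so
medians and IQRs reproduce across statistical environments.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .census import GenomeCensus
from .trna_io import DOMAINS, GenomeMetadata

__all__ = [
    "PervasivenessMatrix",
    "GROUP_LABELS",
    "summarize_domain",
    "mean_counts_by",
    "pervasiveness",
    "classify_groups",
    "venn_high_pervasiveness",
    "gene_density",
    "compare_groups",
    "scaling_analysis",
]

log = logging.getLogger(__name__)

GROUP_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon", "other")

_SCALING_VARS = (
    "genome_size_mb",
    "total_trna",
    "protein_coding_genes",
    "repertoire_size",
    "pseudogene_count",
)


def _meta_map(metadata: Iterable[GenomeMetadata]) -> dict[str, GenomeMetadata]:
    return {m.genome_id: m for m in metadata}


@dataclass
class PervasivenessMatrix:
    """Per-domain pervasiveness of isotype–anticodon combinations.

    ``fraction``: DataFrame indexed by (isotype, anticodon), one column
    per domain, cells in [0, 1] — the fraction of the domain's genomes
    with at least one functional copy.  ``mean_cn``: same shape, mean
    copy number over all genomes of the domain (zeros included).
    ``n_genomes``: per-domain denominators.
    """

    fraction: pd.DataFrame
    mean_cn: pd.DataFrame
    n_genomes: pd.Series

    @property
    def combinations(self) -> list[tuple[str, str]]:
        return list(self.fraction.index)


def summarize_domain(
    censuses: Sequence[GenomeCensus],
    metadata: Iterable[GenomeMetadata],
    metrics: Sequence[str] = ("total_trna", "repertoire_size", "pseudogene_count"),
    by: str = "domain",
) -> pd.DataFrame:
    """Per-domain (or per-group) summary statistics of census metrics.

    Returns a tidy frame with n, mean, sd, se (= sd/√n), median and IQR
    (Q3 − Q1) per (grouping, metric).  Single-genome groups report sd/se
    as missing, never zero.  Empty domains are simply absent (a warning
    is logged).
    """
    mm = _meta_map(metadata)
    rows = []
    for c in censuses:
        m = mm.get(c.genome_id)
        if m is None:
            log.warning("census %s has no metadata; skipped", c.genome_id)
            continue
        rec = {"domain": m.domain, "group": m.group}
        for metric in metrics:
            rec[metric] = getattr(c, metric)
        rows.append(rec)
    df = pd.DataFrame(rows)
    if by == "domain":
        seen = set(df["domain"]) if not df.empty else set()
        for d in DOMAINS:
            if d not in seen:
                log.warning("domain %s has no genomes; omitted from summary", d)
    out = []
    for key, sub in df.groupby(by):
        for metric in metrics:
            v = sub[metric].to_numpy(dtype=float)
            n = len(v)
            sd = float(np.std(v, ddof=1)) if n > 1 else math.nan
            q1, q3 = np.percentile(v, [25, 75])
            out.append(
                {
                    by: key,
                    "metric": metric,
                    "n": n,
                    "mean": float(np.mean(v)),
                    "sd": sd,
                    "se": sd / math.sqrt(n) if n > 1 else math.nan,
                    "median": float(np.median(v)),
                    "iqr": float(q3 - q1),
                }
            )
    return pd.DataFrame(out)


def mean_counts_by(
    censuses: Sequence[GenomeCensus],
    metadata: Iterable[GenomeMetadata],
    key: str = "anticodon",
) -> pd.DataFrame:
    """Mean copy number per anticodon (or isotype) per domain.

    Zeros are included: a genome without the anticodon contributes 0 to
    the domain mean.
    """
    attr = {"anticodon": "counts_by_anticodon", "isotype": "counts_by_isotype"}[key]
    mm = _meta_map(metadata)
    by_domain: dict[str, list[GenomeCensus]] = {}
    for c in censuses:
        m = mm.get(c.genome_id)
        if m is not None:
            by_domain.setdefault(m.domain, []).append(c)
    keys = sorted({k for c in censuses for k in getattr(c, attr)})
    data = {}
    for d, cs in by_domain.items():
        data[d] = [
            float(np.mean([getattr(c, attr).get(k, 0) for c in cs])) for k in keys
        ]
    return pd.DataFrame(data, index=pd.Index(keys, name=key))


def pervasiveness(
    censuses: Sequence[GenomeCensus],
    metadata: Iterable[GenomeMetadata],
    domains: Sequence[str] = DOMAINS,
) -> PervasivenessMatrix:
    """Build the per-domain pervasiveness matrix over observed combinations."""
    mm = _meta_map(metadata)
    by_domain: dict[str, list[GenomeCensus]] = {d: [] for d in domains}
    for c in censuses:
        m = mm.get(c.genome_id)
        if m is not None and m.domain in by_domain:
            by_domain[m.domain].append(c)
    for d, cs in by_domain.items():
        if not cs:
            raise ValueError(f"no genomes in domain {d}")

    combos = sorted({combo for c in censuses for combo in c.combinations})
    idx = pd.MultiIndex.from_tuples(combos, names=["isotype", "anticodon"])
    frac = pd.DataFrame(0.0, index=idx, columns=list(domains))
    mean_cn = pd.DataFrame(0.0, index=idx, columns=list(domains))
    n_genomes = pd.Series({d: len(cs) for d, cs in by_domain.items()})

    for d, cs in by_domain.items():
        n = len(cs)
        for combo in combos:
            counts = [c.counts_by_combination.get(combo, 0) for c in cs]
            frac.loc[combo, d] = sum(1 for x in counts if x >= 1) / n
            mean_cn.loc[combo, d] = float(np.mean(counts))
    return PervasivenessMatrix(fraction=frac, mean_cn=mean_cn, n_genomes=n_genomes)


def classify_groups(
    pm: PervasivenessMatrix,
    high: float = 0.70,
    low: float = 0.30,
    domains: tuple[str, str, str] = ("Eukarya", "Archaea", "Bacteria"),
) -> dict[tuple[str, str], str]:
    """Greek-letter universality classes for each combination.

    With pervasiveness cells (EUK, ARC, BAC):

    * alpha   — all three > ``high`` (near-universal);
    * beta    — EUK > high and ARC > high, BAC ≤ low;
    * gamma   — ARC > high and BAC > high, EUK ≤ low;
    * delta   — EUK > high, ARC ≤ low and BAC ≤ low;
    * epsilon — all three ≤ low (rare or absent everywhere);
    * other   — any remaining mixed pattern.

    Labels are exhaustive and mutually exclusive by construction.
    """
    if high <= low:
        raise ValueError(f"high threshold ({high}) must exceed low ({low})")
    euk_d, arc_d, bac_d = domains
    labels: dict[tuple[str, str], str] = {}
    for combo in pm.combinations:
        euk = pm.fraction.loc[combo, euk_d]
        arc = pm.fraction.loc[combo, arc_d]
        bac = pm.fraction.loc[combo, bac_d]
        if euk > high and arc > high and bac > high:
            lab = "alpha"
        elif euk > high and arc > high and bac <= low:
            lab = "beta"
        elif arc > high and bac > high and euk <= low:
            lab = "gamma"
        elif euk > high and arc <= low and bac <= low:
            lab = "delta"
        elif euk <= low and arc <= low and bac <= low:
            lab = "epsilon"
        else:
            lab = "other"
        labels[combo] = lab
    return labels


def venn_high_pervasiveness(
    pm: PervasivenessMatrix, threshold: float = 0.70
) -> dict[frozenset[str], int]:
    """Counts of combinations above ``threshold`` pervasiveness, per Venn region.

    Returns a mapping from the set of domains (as a frozenset) to the
    number of combinations exclusive to exactly that set of domains; the
    seven region counts sum to the size of the union.
    """
    high_sets = {
        d: {c for c in pm.combinations if pm.fraction.loc[c, d] > threshold}
        for d in pm.fraction.columns
    }
    doms = list(high_sets)
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(doms) + 1):
        for inside in itertools.combinations(doms, r):
            members = set.intersection(*(high_sets[d] for d in inside))
            for d in doms:
                if d not in inside:
                    members -= high_sets[d]
            regions[frozenset(inside)] = len(members)
    return regions


def gene_density(
    metadata: Iterable[GenomeMetadata], censuses: Sequence[GenomeCensus]
) -> pd.DataFrame:
    """Per-genome tRNA and protein-coding gene densities (loci per Mb)."""
    mm = _meta_map(metadata)
    rows = []
    for c in censuses:
        m = mm.get(c.genome_id)
        if m is None:
            log.warning("genome %s lacks metadata (size); skipped", c.genome_id)
            continue
        rows.append(
            {
                "genome_id": c.genome_id,
                "domain": m.domain,
                "group": m.group,
                "genome_size_mb": m.genome_size_mb,
                "total_trna": c.total_trna,
                "trna_density": c.total_trna / m.genome_size_mb,
                "protein_density": m.protein_coding_genes / m.genome_size_mb,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    x: Sequence[float], y: Sequence[float]
) -> dict[str, tuple[float, float]]:
    """Welch two-sample t-test and Mann–Whitney U test, two-sided.

    Welch uses Satterthwaite degrees of freedom and requires n ≥ 2 per
    sample with non-degenerate pooled variance (an explicit error is
    raised when both samples have zero variance, rather than NaN).  The
    U test uses exact enumeration when both samples have n ≤ 20 and no
    ties, and the tie-corrected normal approximation (with continuity
    correction) otherwise.  U is reported for the first sample, so
    swapping the samples maps U → n_x·n_y − U.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("Welch t-test requires n >= 2 in each sample")
    if np.var(xa, ddof=1) == 0 and np.var(ya, ddof=1) == 0:
        raise ValueError("both samples have zero variance; Welch t undefined")
    t_stat, t_p = stats.ttest_ind(xa, ya, equal_var=False)

    has_ties = len(np.unique(np.concatenate([xa, ya]))) < len(xa) + len(ya)
    method = "exact" if (len(xa) <= 20 and len(ya) <= 20 and not has_ties) else "asymptotic"
    u_stat, u_p = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return {
        "welch_t": (float(t_stat), float(t_p)),
        "mann_whitney": (float(u_stat), float(u_p)),
    }


def scaling_analysis(
    metadata: Iterable[GenomeMetadata],
    censuses: Sequence[GenomeCensus],
    variables: Sequence[str] = _SCALING_VARS,
) -> pd.DataFrame:
    """Pairwise scaling among genome-size and census variables.

    For each variable pair, overall and per domain: Spearman rank
    correlation (with p-value) on raw values, and the least-squares
    slope/intercept of log10(y) on log10(x) restricted to strictly
    positive values.  Pairs with fewer than 3 points are skipped with a
    warning.
    """
    mm = _meta_map(metadata)
    rows = []
    for c in censuses:
        m = mm.get(c.genome_id)
        if m is None:
            continue
        rows.append(
            {
                "domain": m.domain,
                "genome_size_mb": m.genome_size_mb,
                "protein_coding_genes": m.protein_coding_genes,
                "total_trna": c.total_trna,
                "repertoire_size": c.repertoire_size,
                "pseudogene_count": c.pseudogene_count,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    scopes = [("all", df)] + [(d, sub) for d, sub in df.groupby("domain")]
    for xvar, yvar in itertools.combinations(variables, 2):
        for scope, sub in scopes:
            xv = sub[xvar].to_numpy(dtype=float)
            yv = sub[yvar].to_numpy(dtype=float)
            if len(xv) < 3:
                log.warning("pair (%s, %s) in %s: < 3 points, skipped", xvar, yvar, scope)
                continue
            if np.all(xv == xv[0]) or np.all(yv == yv[0]):
                # a constant margin carries no rank signal: report 0, not NaN
                rho, rho_p = 0.0, 1.0
            else:
                rho, rho_p = stats.spearmanr(xv, yv)
            pos = (xv > 0) & (yv > 0)
            if pos.sum() >= 3 and not np.all(xv[pos] == xv[pos][0]):
                slope, intercept = np.polyfit(np.log10(xv[pos]), np.log10(yv[pos]), 1)
            else:
                slope, intercept = math.nan, math.nan
            out.append(
                {
                    "scope": scope,
                    "x": xvar,
                    "y": yvar,
                    "n": len(xv),
                    "spearman_rho": float(rho),
                    "spearman_p": float(rho_p),
                    "loglog_slope": float(slope),
                    "loglog_intercept": float(intercept),
                }
            )
    return pd.DataFrame(out)
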