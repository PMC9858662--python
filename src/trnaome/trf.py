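"""tRNA-derived fragment (tRF) classification and pool statistics.

Small RNAs cleaved from tRNAs fall into three positional classes:

* tRF-5 — cut from the 5' end of the mature tRNA (fragment is an exact
  prefix of a mature sequence);
* tRF-3 — cut from the 3' end (exact suffix of a mature sequence; the
  post-transcriptionally appended CCA tail is tried both ways);
* tRF-1 — cut from the 3' trailer of the primary transcript (exact
  prefix of a trailer sequence, downstream of the gene).

Matching is exact (fragments derive from exact genomic sequence); a
fragment matching more than one class is assigned by the fixed priority
tRF-5 > tRF-3 > tRF-1 and flagged ambiguous, so pool totals are
conserved.  Classified fragments are 13–38 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MIN_TRF_LENGTH",
    "MAX_TRF_LENGTH",
    "TRF_TYPES",
    "TRNAModel",
    "TRFRecord",
    "classify_fragment",
    "classify_pool",
    "verify_record",
    "redundancy_stats",
    "trf_census_correlation",
    "length_spectrum",
]

log = logging.getLogger(__name__)

MIN_TRF_LENGTH = 13
MAX_TRF_LENGTH = 38
TRF_TYPES = ("tRF-1", "tRF-3", "tRF-5")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TRNAModel:
    """A mature tRNA sequence plus its genomic 3' trailer (DNA space)."""

    trna_id: str
    mature_seq: str
    trailer_seq: str

    def __post_init__(self) -> None:
        if len(self.mature_seq) < 60:
            raise ValueError(f"{self.trna_id}: mature sequence shorter than 60 nt")
        if len(self.trailer_seq) < 1:
            raise ValueError(f"{self.trna_id}: empty trailer sequence")


@dataclass
class TRFRecord:
    fragment_seq: str
    trf_type: str  # tRF-1 / tRF-3 / tRF-5 / unclassified
    source_trna_ids: frozenset[str] = frozenset()
    ambiguous: bool = False
    via_cca: bool = False  # tRF-3 matched only after appending CCA

    @property
    def length(self) -> int:
        return len(self.fragment_seq)


def _norm(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def classify_fragment(
    fragment: str, models: Sequence[TRNAModel], min_length: int = MIN_TRF_LENGTH
) -> TRFRecord:
    """Assign one fragment to a tRF class by exact end-matching.

    Sources accumulate over all models matching the assigned class.
    Raises ``ValueError`` for fragments below ``min_length``.
    """
    frag = _norm(fragment)
    if len(frag) < min_length:
        raise ValueError(
            f"fragment of {len(frag)} nt rejected: below minimum {min_length}"
        )
    hits5: set[str] = set()
    hits3: set[str] = set()
    hits3_cca_only: set[str] = set()
    hits1: set[str] = set()
    for m in models:
        mature = _norm(m.mature_seq)
        if mature.startswith(frag):
            hits5.add(m.trna_id)
        if mature.endswith(frag):
            hits3.add(m.trna_id)
        elif (mature + "CCA").endswith(frag):
            hits3_cca_only.add(m.trna_id)
        if _norm(m.trailer_seq).startswith(frag):
            hits1.add(m.trna_id)

    all3 = hits3 | hits3_cca_only
    matched = [t for t, hits in (("tRF-5", hits5), ("tRF-3", all3), ("tRF-1", hits1)) if hits]
    if not matched:
        return TRFRecord(frag, UNCLASSIFIED)
    trf_type = matched[0]  # fixed priority tRF-5 > tRF-3 > tRF-1
    sources = {"tRF-5": hits5, "tRF-3": all3, "tRF-1": hits1}[trf_type]
    return TRFRecord(
        frag,
        trf_type,
        source_trna_ids=frozenset(sources),
        ambiguous=len(matched) > 1,
        via_cca=trf_type == "tRF-3" and not hits3,
    )


def classify_pool(
    fragments: Mapping[str, str] | Iterable[str],
    models: Sequence[TRNAModel],
    min_length: int = MIN_TRF_LENGTH,
) -> tuple[list[TRFRecord], list[str]]:
    """Classify a fragment pool; returns (records, rejected-too-short).

    Classification is per-fragment and therefore independent of both
    fragment and model ordering.
    """
    seqs = list(fragments.values()) if isinstance(fragments, Mapping) else list(fragments)
    records, rejected = [], []
    for s in seqs:
        try:
            records.append(classify_fragment(s, models, min_length=min_length))
        except ValueError:
            rejected.append(_norm(s))
    if rejected:
        log.info("%d fragment(s) rejected below %d nt", len(rejected), min_length)
    return records, rejected


def verify_record(record: TRFRecord, models_by_id: Mapping[str, TRNAModel]) -> bool:
    """Re-find the fragment at the claimed position of every claimed source."""
    if record.trf_type == UNCLASSIFIED:
        return True
    for tid in record.source_trna_ids:
        m = models_by_id[tid]
        mature = _norm(m.mature_seq)
        if record.trf_type == "tRF-5" and not mature.startswith(record.fragment_seq):
            return False
        if record.trf_type == "tRF-3" and not (mature + "CCA").endswith(record.fragment_seq):
            return False
        if record.trf_type == "tRF-1" and not _norm(m.trailer_seq).startswith(record.fragment_seq):
            return False
    return True


def redundancy_stats(records: Sequence[TRFRecord]) -> dict:
    """Sequence-redundancy summary of a classified pool.

    ``unique`` counts distinct fragment sequences; ``unique_fraction`` =
    unique/total.  Per-type unique counts are over distinct sequences
    (a sequence counts once per type it was assigned).
    """
    total = len(records)
    if total == 0:
        return {"total": 0, "unique": 0, "unique_fraction": 0.0,
                "per_type_unique": {t: 0 for t in TRF_TYPES}}
    unique = len({r.fragment_seq for r in records})
    per_type = {
        t: len({r.fragment_seq for r in records if r.trf_type == t})
        for t in TRF_TYPES
    }
    return {
        "total": total,
        "unique": unique,
        "unique_fraction": unique / total,
        "per_type_unique": per_type,
    }


def trf_census_correlation(
    trf_totals: Mapping[str, float], trna_cn: Mapping[str, float]
) -> pd.DataFrame:
    """Spearman correlation of per-species tRF counts with tRNA gene counts.

    ``trf_totals`` may be total or unique counts; species present in
    both mappings are used.  Requires at least 3 shared species.  A
    constant margin makes the correlation undefined → reported missing.
    """
    species = sorted(set(trf_totals) & set(trna_cn))
    if len(species) < 3:
        raise ValueError(f"need >= 3 species, got {len(species)}")
    x = np.array([trna_cn[s] for s in species], dtype=float)
    y = np.array([trf_totals[s] for s in species], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        rho, p = np.nan, np.nan
    else:
        rho, p = stats.spearmanr(x, y)
    return pd.DataFrame(
        [{"n_species": len(species), "spearman_rho": rho, "spearman_p": p}]
    )


def length_spectrum(records: Sequence[TRFRecord]) -> pd.DataFrame:
    """Per-type length histogram over non-redundant sequences.

    Returns a tidy frame (trf_type, length, count) plus the per-type
    median length; duplicated sequences count once.
    """
    rows = []
    for t in TRF_TYPES:
        seqs = {r.fragment_seq for r in records if r.trf_type == t}
        if not seqs:
            continue
        lengths = sorted(len(s) for s in seqs)
        med = float(np.median(lengths))
        for L in sorted(set(lengths)):
            rows.append(
                {"trf_type": t, "length": L,
                 "count": lengths.count(L), "type_median": med}
            )
    return pd.DataFrame(rows, columns=["trf_type", "length", "count", "type_median"])
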