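"""Per-region nucleotide composition, A+T content and AT/GC strand skew.

Skews follow the usual definitions AT skew = (A - T)/(A + T) and
GC skew = (G - C)/(G + C).  ``N`` counts toward region length but is excluded
from every composition denominator, so skews stay well defined on records
with ambiguity codes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .io import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    MitoRecord,
    extract_feature_seq,
)

__all__ = [
    "BaseCounts",
    "RegionStats",
    "REGIONS",
    "base_counts",
    "at_skew",
    "gc_skew",
    "at_percent",
    "region_stats",
    "stats_table",
]

#: region label -> feature kind (``whole_genome`` has no features)
REGIONS = {
    "whole_genome": None,
    "PCG": PCG,
    "tRNA": TRNA,
    "rRNA": RRNA,
    "control_region": CONTROL_REGION,
}

_STRANDS = {"+": "H", "-": "L", "both": None}


class BaseCounts(NamedTuple):
    A: int
    T: int
    G: int
    C: int

    @property
    def total(self) -> int:
        return self.A + self.T + self.G + self.C

    def __add__(self, other: "BaseCounts") -> "BaseCounts":  # type: ignore[override]
        return BaseCounts(self.A + other.A, self.T + other.T,
                          self.G + other.G, self.C + other.C)


def base_counts(seq: str) -> BaseCounts:
    """Exact A/T/G/C tallies; ``N`` (and anything else) is ignored."""
    c = Counter(seq.upper())
    return BaseCounts(c["A"], c["T"], c["G"], c["C"])


def at_skew(counts: BaseCounts) -> float | None:
    """(A - T)/(A + T); ``None`` when A + T == 0."""
    denom = counts.A + counts.T
    return None if denom == 0 else (counts.A - counts.T) / denom


def gc_skew(counts: BaseCounts) -> float | None:
    """(G - C)/(G + C); ``None`` when G + C == 0."""
    denom = counts.G + counts.C
    return None if denom == 0 else (counts.G - counts.C) / denom


def at_percent(counts: BaseCounts) -> float | None:
    """A+T content as a percentage of unambiguous bases."""
    total = counts.total
    return None if total == 0 else 100.0 * (counts.A + counts.T) / total


@dataclass(frozen=True)
class RegionStats:
    """Composition summary for one (record, region, strand-class) cell."""

    record: str
    region: str
    strand_class: str  # "+", "-" or "both"
    length: int
    counts: BaseCounts

    @property
    def at_percent(self) -> float | None:
        return at_percent(self.counts)

    @property
    def at_skew(self) -> float | None:
        return at_skew(self.counts)

    @property
    def gc_skew(self) -> float | None:
        return gc_skew(self.counts)


def region_stats(record: MitoRecord, region: str,
                 strand_class: str = "both") -> RegionStats:
    """Composition of one region/strand class of ``record``.

    Strand-class regions are computed on gene-oriented (sense) sequences:
    features on the "-" strand are reverse-complemented before counting, so
    a minority-strand gene class reports the skew of the genes as read.
    ``whole_genome`` uses the record sequence exactly as written.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; "
                         f"expected one of {sorted(REGIONS)}")
    if strand_class not in _STRANDS:
        raise ValueError(f"unknown strand class {strand_class!r}")
    if region == "whole_genome":
        seq = record.sequence
    else:
        feats = record.features_of(REGIONS[region], _STRANDS[strand_class])
        if not feats:
            raise ValueError(
                f"record {record.id!r} has no {region} features on strand "
                f"class {strand_class!r}")
        seq = "".join(extract_feature_seq(record, f) for f in feats)
    return RegionStats(record=record.id, region=region,
                       strand_class=strand_class, length=len(seq),
                       counts=base_counts(seq))


_DEFAULT_ROWS = [
    ("whole_genome", "both"),
    ("PCG", "+"), ("PCG", "-"),
    ("tRNA", "+"), ("tRNA", "-"),
    ("rRNA", "+"), ("rRNA", "-"),
]


def stats_table(records: Iterable[MitoRecord],
                include_control_region: bool = False) -> pd.DataFrame:
    """Composition report, one row per (record, region, strand class).

    Columns: record, region, strand, length_bp, AT_pct, AT_skew, GC_skew.
    AT% is rounded to 1 decimal and skews to 3, matching the conventional
    report precision; rows whose region/strand combination is absent from a
    record are omitted.
    """
    rows = list(_DEFAULT_ROWS)
    if include_control_region:
        rows.append(("control_region", "both"))
    out = []
    for rec in records:
        for region, strand in rows:
            try:
                st = region_stats(rec, region, strand)
            except ValueError:
                continue
            out.append({
                "record": st.record,
                "region": st.region,
                "strand": st.strand_class,
                "length_bp": st.length,
                "AT_pct": None if st.at_percent is None
                else round(st.at_percent, 1),
                "AT_skew": None if st.at_skew is None
                else round(st.at_skew, 3),
                "GC_skew": None if st.gc_skew is None
                else round(st.gc_skew, 3),
            })
    return pd.DataFrame(
        out, columns=["record", "region", "strand", "length_bp",
                      "AT_pct", "AT_skew", "GC_skew"])
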