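"""Codon usage under the invertebrate mitochondrial genetic code.

Counting, RSCU (relative synonymous codon usage), translation, and
start/stop-codon classification including the incomplete T / TA stops that
are completed by polyadenylation in metazoan mitochondria.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "INVERTEBRATE_MITO_TABLE_ID",
    "AMINO_ACID",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "CodonCounts",
    "CodonUsageTable",
    "CodonSignature",
    "codon_counts",
    "rscu",
    "classify_start_stop",
    "translate_mito",
    "rscu_table",
]

#: NCBI translation table 5 (invertebrate mitochondrial):
#: AGA/AGG = Ser, AUA = Met, UGA = Trp.
INVERTEBRATE_MITO_TABLE_ID = 5

_TABLE = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID]

STOP_CODONS = frozenset(_TABLE.stop_codons)  # {'TAA', 'TAG'}

#: codon (DNA) -> one-letter residue; stops map to '*'
AMINO_ACID: dict[str, str] = dict(_TABLE.forward_table)
AMINO_ACID.update({c: "*" for c in STOP_CODONS})

#: residue -> tuple of synonymous codons (sense codons only).  Under this
#: code Leu has 6 codons and Ser has 8 (TCN plus all four AGN).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_CANONICAL_STARTS = frozenset(("ATA", "ATT", "ATG", "ATC"))


@dataclass(frozen=True)
class CodonCounts:
    """Codon tallies with stop codons kept in a separate bucket."""

    sense: Counter
    stop: Counter
    ambiguous: int = 0

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(self.sense + other.sense, self.stop + other.stop,
                           self.ambiguous + other.ambiguous)

    def total(self) -> int:
        return sum(self.sense.values()) + sum(self.stop.values())


def codon_counts(cds_seqs: Iterable[str]) -> CodonCounts:
    """Tally complete codons of in-frame CDS sequences.

    Each sequence is read in frame from its first base; a trailing partial
    codon (1-2 bases, e.g. an incomplete stop) is dropped.  Codons containing
    ``N`` go to an ``ambiguous`` bucket; stop codons are tallied separately
    so they never enter RSCU families.
    """
    sense: Counter = Counter()
    stop: Counter = Counter()
    ambiguous = 0
    for seq in cds_seqs:
        s = seq.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if "N" in codon:
                ambiguous += 1
            elif codon in STOP_CODONS:
                stop[codon] += 1
            else:
                sense[codon] += 1
    return CodonCounts(sense=sense, stop=stop, ambiguous=ambiguous)


@dataclass(frozen=True)
class CodonUsageTable:
    """Counts plus RSCU for every sense codon.

    ``rscu[c]`` is ``count(c) * |F| / sum of counts over c's synonymous
    family F``, or ``None`` for every codon of an unobserved family.
    """

    counts: Mapping[str, int]
    rscu: Mapping[str, float | None]
    amino_acid: Mapping[str, str]


def rscu(counts: CodonCounts) -> CodonUsageTable:
    """Relative synonymous codon usage from pooled codon counts."""
    values: dict[str, float | None] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        family_total = sum(counts.sense.get(c, 0) for c in family)
        for c in family:
            if family_total == 0:
                values[c] = None
            else:
                values[c] = counts.sense.get(c, 0) * len(family) / family_total
    count_map = {c: counts.sense.get(c, 0)
                 for fam in SYNONYMOUS_FAMILIES.values() for c in fam}
    aa_map = {c: AMINO_ACID[c] for c in count_map}
    return CodonUsageTable(counts=count_map, rscu=values, amino_acid=aa_map)


@dataclass(frozen=True)
class CodonSignature:
    """Start/stop classification of one CDS."""

    gene: str | None
    start_codon: str
    start_canonical: bool  # matches ATN
    stop_codon: str  # "TAA"/"TAG", incomplete "T"/"TA", or last codon seen
    stop_kind: str  # "complete" | "incomplete" | "non_canonical"


def classify_start_stop(cds: str, gene: str | None = None) -> CodonSignature:
    """Classify the start and stop codon of a gene-oriented CDS.

    The start is the first three bases, canonical iff it matches ATN.  The
    stop is the last complete codon when it is TAA/TAG and the length is a
    multiple of three; otherwise a trailing T or TA is reported as an
    incomplete stop; anything else is non-canonical.
    """
    s = cds.upper()
    if len(s) < 6:
        raise ValueError(f"CDS shorter than 6 bases ({len(s)})")
    start = s[:3]
    rem = len(s) % 3
    tail = s[len(s) - rem:] if rem else s[-3:]
    if rem == 0 and tail in STOP_CODONS:
        stop, kind = tail, "complete"
    elif rem and tail in ("T", "TA"):
        stop, kind = tail, "incomplete"
    else:
        stop, kind = tail, "non_canonical"
    return CodonSignature(gene=gene, start_codon=start,
                          start_canonical=start in _CANONICAL_STARTS,
                          stop_codon=stop, stop_kind=kind)


def translate_mito(cds: str) -> str:
    """Translate an in-frame CDS under the invertebrate mitochondrial code.

    A trailing partial codon is dropped; a terminal stop renders as ``*``.
    Internal stop codons translate as ``*`` too but raise a warning listing
    their codon positions, since they normally flag a frame or annotation
    error.  Codons containing ``N`` render as ``X``.
    """
    s = cds.upper()
    protein = []
    internal_stops = []
    n_codons = (len(s)) // 3
    for i in range(n_codons):
        codon = s[3 * i:3 * i + 3]
        if "N" in codon:
            protein.append("X")
            continue
        aa = AMINO_ACID.get(codon)
        if aa is None:
            raise ValueError(f"unrecognized codon {codon!r} at position {i + 1}")
        if aa == "*" and i < n_codons - 1:
            internal_stops.append(i + 1)
        protein.append(aa)
    if internal_stops:
        warnings.warn(
            f"internal stop codon(s) at codon position(s) {internal_stops}",
            stacklevel=2)
    return "".join(protein)


def _to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def rscu_table(usage: CodonUsageTable, record: str | None = None,
               rna_display: bool = True) -> pd.DataFrame:
    """Long-format RSCU report: codon, amino_acid, count, RSCU."""
    rows = []
    for codon in sorted(usage.counts):
        rows.append({
            "record": record,
            "codon": _to_rna(codon) if rna_display else codon,
            "amino_acid": usage.amino_acid[codon],
            "count": usage.counts[codon],
            "RSCU": None if usage.rscu[codon] is None
            else round(usage.rscu[codon], 3),
        })
    cols = ["record", "codon", "amino_acid", "count", "RSCU"]
    df = pd.DataFrame(rows, columns=cols)
    if record is None:
        df = df.drop(columns=["record"])
    return df
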