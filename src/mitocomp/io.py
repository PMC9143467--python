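"""Annotated mitogenome records: data model plus GenBank / FASTA+TSV I/O.

The record model is deliberately thin: a sequence string on the published
strand plus a flat list of gene features with 1-based inclusive coordinates
(the GenBank convention).  All coordinate arithmetic elsewhere in the package
is 0-based half-open; the conversion happens only in this module.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitoRecord",
    "PCG",
    "TRNA",
    "RRNA",
    "CONTROL_REGION",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "GENE_NAME_ALIASES",
    "normalize_gene_name",
    "reverse_complement",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "extract_feature_seq",
]

# feature kinds
PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"

#: 13 protein-coding genes in canonical insect mitochondrial genome order.
PCG_NAMES = [
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "ND3", "ND5", "ND4", "ND4L", "ND6", "CytB", "ND1",
]

#: 22 tRNAs; the two leucine/serine copies carry disambiguating suffixes
#: (trnL1 = CUN family, trnL2 = UUR; trnS1 = AGN, trnS2 = UCN).
TRNA_NAMES = [
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
]

RRNA_NAMES = ["12S", "16S"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_BASES = frozenset("ACGTN")

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: User-extensible mapping of common GenBank gene-name dialects to the
#: canonical vocabulary used throughout the package.
GENE_NAME_ALIASES: dict[str, str] = {
    "COX1": "COI", "CO1": "COI", "COXI": "COI", "COI": "COI",
    "COX2": "COII", "CO2": "COII", "COXII": "COII", "COII": "COII",
    "COX3": "COIII", "CO3": "COIII", "COXIII": "COIII", "COIII": "COIII",
    "NAD1": "ND1", "NADH1": "ND1", "ND1": "ND1",
    "NAD2": "ND2", "NADH2": "ND2", "ND2": "ND2",
    "NAD3": "ND3", "NADH3": "ND3", "ND3": "ND3",
    "NAD4": "ND4", "NADH4": "ND4", "ND4": "ND4",
    "NAD4L": "ND4L", "NADH4L": "ND4L", "ND4L": "ND4L",
    "NAD5": "ND5", "NADH5": "ND5", "ND5": "ND5",
    "NAD6": "ND6", "NADH6": "ND6", "ND6": "ND6",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPASE 8": "ATP8",
    "CYTB": "CytB", "COB": "CytB", "CYB": "CytB", "CYT B": "CytB",
    "CYTOCHROME B": "CytB",
    "RRNL": "16S", "L-RRNA": "16S", "16S": "16S", "16S RRNA": "16S",
    "16S RIBOSOMAL RNA": "16S", "LARGE SUBUNIT RIBOSOMAL RNA": "16S",
    "RRNS": "12S", "S-RRNA": "12S", "12S": "12S", "12S RRNA": "12S",
    "12S RIBOSOMAL RNA": "12S", "SMALL SUBUNIT RIBOSOMAL RNA": "12S",
    "CR": "CR", "D-LOOP": "CR", "A+T-RICH REGION": "CR",
    "CONTROL REGION": "CR", "AT-RICH REGION": "CR",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(raw: str, kind: str | None = None,
                        anticodon: str | None = None) -> tuple[str, bool]:
    """Map a raw GenBank gene label onto the canonical 37-gene vocabulary.

    Returns ``(name, known)``; unknown labels are passed through unchanged
    with ``known=False`` so callers can warn but keep the feature.

    tRNA labels accept both one-letter (``trnA``) and product-style
    (``tRNA-Ala``) spellings; the leucine and serine duplicates are
    disambiguated by anticodon when one is supplied, otherwise a bare
    ``trnL``/``trnS`` is returned un-suffixed with ``known=False``.
    """
    label = raw.strip()
    upper = label.upper()
    if upper in GENE_NAME_ALIASES:
        return GENE_NAME_ALIASES[upper], True

    m = re.match(r"^(?:TRN|TRNA[- ]?)([A-Z]{1,3})(\d?)\s*(?:\(([A-Z]{3})\))?$",
                 upper)
    if m and (kind is None or kind == TRNA):
        aa, suffix, codon_family = m.groups()
        if aa in _AA3_TO_1:
            aa = _AA3_TO_1[aa]
        if len(aa) == 1:
            name = f"trn{aa}"
            if aa in ("L", "S"):
                if suffix in ("1", "2"):
                    return name + suffix, True
                resolved = _resolve_ls_suffix(aa, anticodon, codon_family)
                if resolved:
                    return resolved, True
                return name, False
            if name in TRNA_NAMES:
                return name, True
    return label, False


def _resolve_ls_suffix(aa: str, anticodon: str | None,
                       codon_family: str | None) -> str | None:
    """Disambiguate trnL/trnS using the anticodon or a (UUR)/(CUN) tag."""
    if codon_family:
        fam = codon_family.replace("U", "T")
        if aa == "L":
            return "trnL2" if fam in ("TTR", "TTA", "TTG") else "trnL1"
        return "trnS1" if fam.startswith("AG") else "trnS2"
    if anticodon:
        ac = anticodon.upper().replace("U", "T")
        if aa == "L":
            # CUN family reads anticodon UAG; UUR family reads UAA
            return {"TAG": "trnL1", "TAA": "trnL2"}.get(ac)
        return {"GCT": "trnS1", "TCT": "trnS1", "TGA": "trnS2"}.get(ac)
    return None


@dataclass(frozen=True)
class GeneFeature:
    """One gene annotation on a mitogenome record.

    Coordinates are 1-based inclusive on the published strand; features that
    wrap the circular origin carry two or more ``spans`` in reading order.
    ``strand`` is "H" for the strand the record sequence is written in and
    "L" for its complement.
    """

    name: str
    kind: str
    spans: tuple[tuple[int, int], ...]
    strand: str = "H"
    anticodon: str | None = None
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (PCG, TRNA, RRNA, CONTROL_REGION):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if not self.spans:
            raise ValueError("feature needs at least one span")
        for s, e in self.spans:
            if s < 1 or e < s:
                raise ValueError(
                    f"bad span ({s}, {e}) for feature {self.name!r}")

    @classmethod
    def make(cls, name: str, kind: str, start: int, end: int,
             strand: str = "H", **kw) -> "GeneFeature":
        return cls(name=name, kind=kind, spans=((start, end),),
                   strand=strand, **kw)

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.spans)


@dataclass
class MitoRecord:
    """A (usually circular) annotated mitochondrial genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: sequence letters outside ACGTN: "
                f"{sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: feature {f.name!r} span "
                    f"({f.start}, {f.end}) outside sequence of length "
                    f"{len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of(self, kind: str,
                    strand: str | None = None) -> list[GeneFeature]:
        return [f for f in self.features
                if f.kind == kind and (strand is None or f.strand == strand)]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"record {self.id!r} has no feature {name!r}")

    def is_canonical(self) -> bool:
        """True when the record has the full 37-gene complement."""
        return (len(self.features_of(PCG)) == 13
                and len(self.features_of(TRNA)) == 22
                and len(self.features_of(RRNA)) == 2
                and len(self.features_of(CONTROL_REGION)) <= 1)


def extract_feature_seq(record: MitoRecord, feature: GeneFeature) -> str:
    """Gene-oriented sub-sequence of ``feature``.

    Strand-H features return the published-strand slice; strand-L features
    return its reverse complement.  Wrap-around features concatenate their
    spans in feature order before orienting.
    """
    parts = []
    for s, e in feature.spans:
        if e > len(record.sequence):
            raise ValueError(
                f"feature {feature.name!r} span ({s}, {e}) outside record "
                f"{record.id!r}")
        parts.append(record.sequence[s - 1:e])
    seq = "".join(parts)
    return reverse_complement(seq) if feature.strand == "L" else seq


# ---------------------------------------------------------------------------
# GenBank I/O

_GB_KIND_FROM_KEY = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA, "D-loop": CONTROL_REGION}
_GB_KEY_FROM_KIND = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", CONTROL_REGION: "D-loop"}


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return None


def _feature_anticodon(feat: SeqFeature) -> str | None:
    vals = feat.qualifiers.get("anticodon")
    if not vals:
        return None
    m = re.search(r"seq\s*:\s*([acgtuACGTU]{3})", str(vals[0]))
    if m:
        return m.group(1).upper().replace("U", "T")
    m = re.fullmatch(r"[acgtuACGTU]{3}", str(vals[0]).strip())
    return m.group(0).upper().replace("U", "T") if m else None


def _from_biopython_feature(feat: SeqFeature, rec_id: str) -> GeneFeature | None:
    key = feat.type
    if key == "misc_feature":
        note = " ".join(str(v) for v in feat.qualifiers.get("note", []))
        if re.search(r"A\s*\+?\s*T[- ]rich|control region|D-loop", note, re.I):
            key = "D-loop"
        else:
            return None
    if key not in _GB_KIND_FROM_KEY:
        return None
    kind = _GB_KIND_FROM_KEY[key]
    spans = tuple((int(p.start) + 1, int(p.end)) for p in feat.location.parts)
    strand = "L" if feat.location.strand == -1 else "H"
    anticodon = _feature_anticodon(feat)
    if kind == CONTROL_REGION:
        name, known = "CR", True
    else:
        raw = _feature_name(feat)
        if raw is None:
            name, known = f"{kind}@{spans[0][0]}", False
        else:
            name, known = normalize_gene_name(raw, kind=kind,
                                              anticodon=anticodon)
        if not known:
            warnings.warn(
                f"record {rec_id}: unrecognized gene label {name!r}; "
                f"keeping raw name", stacklevel=3)
    length = sum(e - s + 1 for s, e in spans)
    incomplete = kind == PCG and length % 3 != 0
    return GeneFeature(name=name, kind=kind, spans=spans, strand=strand,
                       anticodon=anticodon, incomplete_stop=incomplete)


def read_genbank(path: str | Path) -> list[MitoRecord]:
    """Read all records of a GenBank flat file into :class:`MitoRecord` s."""
    records = []
    locus = "<unknown>"
    try:
        for rec in SeqIO.parse(str(path), "genbank"):
            locus = rec.name or rec.id
            feats = []
            for feat in rec.features:
                gf = _from_biopython_feature(feat, rec.id)
                if gf is not None:
                    feats.append(gf)
            circular = rec.annotations.get("topology",
                                           "circular") == "circular"
            records.append(MitoRecord(id=rec.id.split(".")[0] or rec.name,
                                      sequence=str(rec.seq),
                                      circular=circular, features=feats))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(
            f"cannot parse GenBank file {path} (LOCUS {locus}): {exc}"
        ) from exc
    return records


def write_genbank(records: Iterable[MitoRecord], path: str | Path) -> None:
    """Write records as a GenBank flat file (deterministic output)."""
    out = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id[:16],
                       description=f"{rec.id} mitochondrial genome")
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.circular else "linear"
        # fixed date keeps simulator output byte-identical across runs
        sr.annotations["date"] = "01-JAN-2000"
        for f in rec.features:
            locs = [SimpleLocation(s - 1, e, strand=-1 if f.strand == "L" else 1)
                    for s, e in f.spans]
            loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            quals: dict[str, list[str]] = {"gene": [f.name]}
            if f.anticodon:
                quals["anticodon"] = [f"(seq:{f.anticodon.lower()})"]
            sf = SeqFeature(loc, type=_GB_KEY_FROM_KIND[f.kind],
                            qualifiers=quals)
            out_feats = sr.features
            out_feats.append(sf)
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + TSV feature-table I/O

def read_fasta(path: str | Path,
               feature_table: str | Path | None = None) -> list[MitoRecord]:
    """Read plain FASTA; an optional TSV sidecar supplies the annotation."""
    feats_by_rec: dict[str, list[GeneFeature]] = {}
    if feature_table is not None:
        feats_by_rec = read_feature_table(feature_table)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        records.append(MitoRecord(id=rid, sequence=str(rec.seq),
                                  features=feats_by_rec.get(rid, [])))
    return records


def write_fasta(records: Iterable[MitoRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


_TABLE_COLS = ["record", "gene", "kind", "start", "end", "strand", "anticodon"]


def read_feature_table(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Read the TSV annotation sidecar (record, gene, kind, start, end, strand)."""
    out: dict[str, list[GeneFeature]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            feat = GeneFeature.make(
                name=row["gene"], kind=row["kind"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row.get("strand", "H") or "H",
                anticodon=row.get("anticodon") or None)
            out.setdefault(row["record"], []).append(feat)
    return out


def write_feature_table(records: Iterable[MitoRecord],
                        path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TABLE_COLS)
        for rec in records:
            for f in rec.features:
                w.writerow([rec.id, f.name, f.kind, f.start, f.end,
                            f.strand, f.anticodon or ""])
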