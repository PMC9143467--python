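"""Pairwise genetic distances and threshold-based species delimitation.

Distances are computed on pre-aligned sequences with pairwise deletion:
a site enters a pair's comparison only when both sequences carry an
unambiguous A/C/G/T there.  Two models are provided, the uncorrected
proportion of differing sites (p) and Kimura's two-parameter correction
(k2p).

Delimitation is single linkage: taxa joined by any distance strictly below
the conspecific threshold fall in one cluster; cross-cluster pairs that
share a morphospecies label are flagged as cryptic candidates.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "DistanceMatrix",
    "DelimitationResult",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "delimit",
    "read_alignment",
    "load_vietnamellidae_distances",
    "global_align",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _site_comparison(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, differences, transitions) after pairwise deletion."""
    if len(a) != len(b):
        raise ValueError(
            f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    x, y = _encode(a), _encode(b)
    valid = (x >= 0) & (y >= 0)
    n = int(valid.sum())
    diff = valid & (x != y)
    # A=0/G=2 are even, C=1/T=3 odd: a same-parity difference is a transition
    ts = int((diff & ((x & 1) == (y & 1))).sum())
    return n, int(diff.sum()), ts


def p_distance(a: str, b: str) -> float | None:
    """Proportion of differing sites; ``None`` when no site is comparable."""
    n, d, _ = _site_comparison(a, b)
    return None if n == 0 else d / n


def k2p_distance(a: str, b: str) -> float | None:
    """Kimura two-parameter distance, ``None`` on saturation or no data.

    With transition fraction P and transversion fraction Q over comparable
    sites, d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)).
    """
    n, d, ts = _site_comparison(a, b)
    if n == 0:
        return None
    P = ts / n
    Q = (d - ts) / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


_MODELS = {"p": p_distance, "k2p": k2p_distance}


@dataclass
class DistanceMatrix:
    """Symmetric labelled pairwise-distance matrix (proportion scale)."""

    labels: list[str]
    values: np.ndarray  # square, symmetric, NaN marks undefined entries
    model: str = "p"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def summary(self) -> dict[str, float]:
        """min / max / mean over the n(n-1)/2 off-diagonal values."""
        vals = np.array([d for _, _, d in self.pairs()])
        return {"n_pairs": len(vals), "min": float(np.nanmin(vals)),
                "max": float(np.nanmax(vals)), "mean": float(np.nanmean(vals))}

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels),
                              values=self.values[np.ix_(idx, idx)],
                              model=self.model)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "label"
        df.to_csv(path, sep="\t", float_format="%.6g")

    def write_mega_lower(self, path: str | Path, decimals: int = 3) -> None:
        """Lower-triangle text layout, one numbered row per taxon."""
        with open(path, "w") as fh:
            for i, label in enumerate(self.labels):
                cells = [f"{self.values[i, j]:.{decimals}f}"
                         for j in range(i)]
                fh.write("\t".join([f"{i + 1}", label] + cells) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, model: str = "p") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != labels:
            raise ValueError(f"matrix file {path} is not square-labelled")
        return cls(labels=labels, values=df.to_numpy(dtype=float), model=model)


def distance_matrix(seqs: Mapping[str, str] | Sequence[tuple[str, str]],
                    model: str = "p") -> DistanceMatrix:
    """All pairwise distances among labelled, equal-length aligned sequences."""
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    labels = [l for l, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of p, k2p")
    fn = _MODELS[model]
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = fn(items[i][1], items[j][1])
            d[i, j] = d[j, i] = math.nan if v is None else v
    return DistanceMatrix(labels=labels, values=d, model=model)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned multi-FASTA into an ordered label -> sequence map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate label {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


# ---------------------------------------------------------------------------
# Delimitation


@dataclass
class DelimitationResult:
    """Single-linkage clusters plus per-pair conspecific/cryptic flags."""

    t_intra: float
    clusters: list[list[str]]
    flags: dict[tuple[str, str], str]  # conspecific | cryptic_candidate | distinct
    within_max: dict[tuple[str, ...], float | None]
    between_min: dict[tuple[int, int], tuple[float, tuple[str, str]]]

    def cluster_of(self, label: str) -> int:
        for i, members in enumerate(self.clusters):
            if label in members:
                return i
        raise KeyError(label)

    def to_json_dict(self) -> dict:
        return {
            "t_intra": self.t_intra,
            "clusters": self.clusters,
            "flags": [{"a": a, "b": b, "flag": f}
                      for (a, b), f in sorted(self.flags.items())],
            "evidence": {
                "within_max": [
                    {"cluster": list(k), "max_distance": v}
                    for k, v in self.within_max.items()],
                "between_min": [
                    {"clusters": [list(self.clusters[i]),
                                  list(self.clusters[j])],
                     "min_distance": d, "pair": list(pair)}
                    for (i, j), (d, pair) in sorted(self.between_min.items())],
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")


def delimit(m: DistanceMatrix, t_intra: float = 0.07,
            morphospecies: Mapping[str, str] | None = None) -> DelimitationResult:
    """Single-linkage species delimitation at a conspecific threshold.

    Clusters are the connected components of the graph whose edges are pairs
    with distance strictly below ``t_intra``.  A cross-cluster pair is a
    ``cryptic_candidate`` when both members carry the same morphospecies
    label (genetically divergent yet morphologically assigned to one
    species), otherwise ``distinct``.
    """
    if not 0.0 < t_intra < 1.0:
        raise ValueError(f"t_intra must lie in (0, 1), got {t_intra}")
    bad = [(a, b) for a, b, d in m.pairs() if math.isnan(d)]
    if bad:
        raise ValueError(f"undefined distances for pairs: {bad}")

    parent = list(range(len(m)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            if m.values[i, j] < t_intra:
                parent[find(i)] = find(j)

    comp: dict[int, list[str]] = {}
    for i, label in enumerate(m.labels):
        comp.setdefault(find(i), []).append(label)
    # deterministic: clusters ordered by first member's position in m.labels
    clusters = sorted(comp.values(), key=lambda c: m.labels.index(c[0]))

    idx_of = {l: k for k, members in enumerate(clusters) for l in members}
    flags: dict[tuple[str, str], str] = {}
    between: dict[tuple[int, int], tuple[float, tuple[str, str]]] = {}
    for a, b, d in m.pairs():
        ca, cb = idx_of[a], idx_of[b]
        if ca == cb:
            flags[(a, b)] = "conspecific"
        else:
            same_morpho = (morphospecies is not None
                           and morphospecies.get(a) is not None
                           and morphospecies.get(a) == morphospecies.get(b))
            flags[(a, b)] = "cryptic_candidate" if same_morpho else "distinct"
            key = (min(ca, cb), max(ca, cb))
            if key not in between or d < between[key][0]:
                between[key] = (d, (a, b))

    within_max: dict[tuple[str, ...], float | None] = {}
    for members in clusters:
        if len(members) < 2:
            within_max[tuple(members)] = None
        else:
            within_max[tuple(members)] = max(
                m.get(a, b) for i, a in enumerate(members)
                for b in members[i + 1:])
    return DelimitationResult(t_intra=t_intra, clusters=clusters, flags=flags,
                              within_max=within_max, between_min=between)


# ---------------------------------------------------------------------------
# Shipped fixture: published whole-mitogenome distances within Vietnamellidae


def load_vietnamellidae_distances() -> tuple[DistanceMatrix, dict[str, str]]:
    """The published 6-taxon Vietnamellidae whole-mitogenome distance matrix.

    Returns the matrix plus a label -> morphospecies map (the four
    populations assigned to *Vietnamella sinensis* share one label).
    """
    pkg = resources.files("mitocomp") / "data"
    with resources.as_file(pkg / "vietnamellidae_mt_distances.tsv") as p:
        m = DistanceMatrix.read_tsv(p)
    morpho: dict[str, str] = {}
    with resources.as_file(pkg / "vietnamellidae_mt_taxa.tsv") as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                morpho[row["label"]] = row["morphospecies"]
    return m, morpho


# ---------------------------------------------------------------------------
# Small global aligner (test helper; not meant for whole mitogenomes)

_MAX_ALIGN_LEN = 2000


def global_align(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment of two short sequences.

    Capped at 2 kb per sequence: the package deliberately does not align
    full mitogenomes; provide a pre-computed alignment for those.
    """
    if len(a) > _MAX_ALIGN_LEN or len(b) > _MAX_ALIGN_LEN:
        raise ValueError(
            f"global_align is limited to sequences <= {_MAX_ALIGN_LEN} bp")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])
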