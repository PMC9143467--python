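"""Synthetic annotated mitogenomes with known ground truth.

The generator builds an ancestral ~15.6 kb circular genome with the
canonical 37-gene insect mitochondrial gene order (13 PCGs, 22 tRNAs,
2 rRNAs, control region), then evolves it along a tree under an HKY
substitution model with per-codon-position rate multipliers.  Stationary
frequencies are chosen from the target A+T content and strand skews, so
minority-strand genes automatically show mirrored skews when read in gene
orientation.  Protein-coding constraint is limited to "no internal stop
codons" (mutations creating one are rejection-resampled).

Everything is driven by a single seeded RNG: a fixed seed reproduces the
output bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .io import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    GeneFeature,
    MitoRecord,
)

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate",
    "expected_p_distance",
    "stationary_frequencies",
    "hky_rate_matrix",
    "planted_partition_tree",
    "random_tree",
]

# base encoding shared with the distance module: A=0, C=1, G=2, T=3
_BASES = np.array(list("ACGT"))
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

# stop codons of the invertebrate mitochondrial code, encoded
_STOP_TAA = (3, 0, 0)
_STOP_TAG = (3, 0, 2)

#: canonical insect mitochondrial gene order (name, kind, strand)
GENOME_ORDER: tuple[tuple[str, str, str], ...] = (
    ("trnI", TRNA, "H"), ("trnQ", TRNA, "L"), ("trnM", TRNA, "H"),
    ("ND2", PCG, "H"), ("trnW", TRNA, "H"), ("trnC", TRNA, "L"),
    ("trnY", TRNA, "L"), ("COI", PCG, "H"), ("trnL2", TRNA, "H"),
    ("COII", PCG, "H"), ("trnK", TRNA, "H"), ("trnD", TRNA, "H"),
    ("ATP8", PCG, "H"), ("ATP6", PCG, "H"), ("COIII", PCG, "H"),
    ("trnG", TRNA, "H"), ("ND3", PCG, "H"), ("trnA", TRNA, "H"),
    ("trnR", TRNA, "H"), ("trnN", TRNA, "H"), ("trnS1", TRNA, "H"),
    ("trnE", TRNA, "H"), ("trnF", TRNA, "L"), ("ND5", PCG, "L"),
    ("trnH", TRNA, "L"), ("ND4", PCG, "L"), ("ND4L", PCG, "L"),
    ("trnT", TRNA, "H"), ("trnP", TRNA, "L"), ("ND6", PCG, "H"),
    ("CytB", PCG, "H"), ("trnS2", TRNA, "H"), ("ND1", PCG, "L"),
    ("trnL1", TRNA, "L"), ("16S", RRNA, "L"), ("trnV", TRNA, "L"),
    ("12S", RRNA, "L"), ("CR", CONTROL_REGION, "H"),
)

# amino-acid codon counts per PCG (start included, stop excluded); sized so
# the default layout lands near 15.6 kb
_PCG_AA_CODONS = {
    "ND2": 325, "COI": 511, "COII": 226, "ATP8": 52, "ATP6": 225,
    "COIII": 261, "ND3": 117, "ND5": 571, "ND4": 445, "ND4L": 97,
    "ND6": 172, "CytB": 378, "ND1": 312,
}

_TRNA_LEN = {
    "trnI": 66, "trnQ": 69, "trnM": 68, "trnW": 67, "trnC": 61,
    "trnY": 70, "trnL2": 65, "trnK": 69, "trnD": 64, "trnG": 63,
    "trnA": 64, "trnR": 65, "trnN": 66, "trnS1": 67, "trnE": 65,
    "trnF": 64, "trnH": 63, "trnT": 64, "trnP": 66, "trnS2": 68,
    "trnL1": 64, "trnV": 66,
}

_RRNA_LEN = {"16S": 1223, "12S": 792}

_BASELINE_LENGTH = 15600


@dataclass
class SimParams:
    """Parameters of one simulation run; ``seed`` fixes all outputs."""

    n_taxa: int = 6
    tree: str | dendropy.Tree | None = None  # newick or tree; random if None
    genome_length: int = _BASELINE_LENGTH
    at_target: float = 0.705
    at_skew_target: float = -0.08
    gc_skew_target: float = -0.21
    rate_multipliers: tuple[float, float, float] = (1.0, 1.0, 5.0)
    kappa: float = 4.0
    species_partition: Mapping[str, str] | None = None
    incomplete_stop_genes: tuple[str, ...] = ("COII", "ND5", "CytB")
    seed: int = 0


@dataclass
class GroundTruth:
    """Known quantities of a simulated data set."""

    tree_newick: str
    labels: list[str]
    path_length: dict[tuple[str, str], float]
    expected_p: dict[tuple[str, str], float]
    species: dict[str, str] | None
    base_counts: dict[str, dict[str, int]]
    ancestor_sequence: str
    pi: tuple[float, float, float, float]  # A, C, G, T
    kappa: float
    rate_multipliers: tuple[float, float, float]
    site_rate_share: dict[float, float]

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def expected_p_for(self, a: str, b: str) -> float:
        return self.expected_p[self.pair(a, b)]

    def path_length_for(self, a: str, b: str) -> float:
        return self.path_length[self.pair(a, b)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree_newick": self.tree_newick,
            "labels": self.labels,
            "path_length": {f"{a}|{b}": v
                            for (a, b), v in sorted(self.path_length.items())},
            "expected_p": {f"{a}|{b}": v
                           for (a, b), v in sorted(self.expected_p.items())},
            "species": self.species,
            "base_counts": self.base_counts,
            "pi": list(self.pi),
            "kappa": self.kappa,
            "rate_multipliers": list(self.rate_multipliers),
            "site_rate_share": {str(k): v
                                for k, v in sorted(self.site_rate_share.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Model pieces


def stationary_frequencies(at: float, at_skew: float,
                           gc_skew: float) -> np.ndarray:
    """Stationary base frequencies (A, C, G, T) hitting the given targets."""
    if not 0.0 < at < 1.0:
        raise ValueError(f"at_target must lie in (0, 1), got {at}")
    if not (-1.0 < at_skew < 1.0 and -1.0 < gc_skew < 1.0):
        raise ValueError("skew targets must lie in (-1, 1)")
    a = at * (1.0 + at_skew) / 2.0
    t = at * (1.0 - at_skew) / 2.0
    g = (1.0 - at) * (1.0 + gc_skew) / 2.0
    c = (1.0 - at) * (1.0 - gc_skew) / 2.0
    pi = np.array([a, c, g, t])
    if (pi <= 0.0).any():
        raise ValueError(
            f"contradictory composition targets (frequencies {pi})")
    return pi


def hky_rate_matrix(pi: np.ndarray, kappa: float) -> np.ndarray:
    """HKY rate matrix normalized to one expected substitution per unit time."""
    if kappa <= 0.0:
        raise ValueError("kappa must be positive")
    n = 4
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = pi[j] * (kappa if transition else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(pi, np.diag(Q)))
    return Q / rate


def expected_p_distance(branch_path_length: float,
                        pi: Sequence[float] | None = None,
                        kappa: float | None = None,
                        rate: float = 1.0) -> float:
    """Expected proportion of differing sites after evolving a path.

    With no frequencies given this is the Jukes-Cantor closed form
    ``3/4 (1 - exp(-4 d / 3))``; otherwise it is computed from the HKY rate
    matrix exponential as ``1 - sum_i pi_i P_ii(d)``.
    """
    d = branch_path_length * rate
    if d < 0.0:
        raise ValueError("path length must be non-negative")
    if pi is None:
        return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    pi = np.asarray(pi, dtype=float)
    Q = hky_rate_matrix(pi, 4.0 if kappa is None else kappa)
    P = expm(Q * d)
    return float(1.0 - np.dot(pi, np.diag(P)))


# ---------------------------------------------------------------------------
# Trees


def random_tree(labels: Sequence[str], rng: np.random.Generator,
                branch_scale: float = 0.03) -> str:
    """Random binary topology with exponential branch lengths, as newick."""
    subtrees = [f"{l}" for l in labels]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        bi = rng.exponential(branch_scale)
        bj = rng.exponential(branch_scale)
        merged = f"({subtrees[i]}:{bi:.6f},{subtrees[j]}:{bj:.6f})"
        subtrees = ([s for k, s in enumerate(subtrees) if k not in (i, j)]
                    + [merged])
    ba = rng.exponential(branch_scale)
    bb = rng.exponential(branch_scale)
    return f"({subtrees[0]}:{ba:.6f},{subtrees[1]}:{bb:.6f});"


def planted_partition_tree(partition: Mapping[str, str],
                           intra: float = 0.01,
                           inter: float = 0.15) -> str:
    """Tree in which same-species tip pairs sit at path distance ``intra``
    and cross-species pairs at exactly ``inter``."""
    if inter <= intra:
        raise ValueError("inter-species distance must exceed intra")
    by_species: dict[str, list[str]] = {}
    for label, sp in partition.items():
        by_species.setdefault(sp, []).append(label)
    stem = (inter - intra) / 2.0
    leaf = intra / 2.0
    parts = []
    for sp in sorted(by_species):
        members = sorted(by_species[sp])
        if len(members) == 1:
            parts.append(f"{members[0]}:{inter / 2.0:.8f}")
        else:
            inner = ",".join(f"{m}:{leaf:.8f}" for m in members)
            parts.append(f"({inner}):{stem:.8f}")
    return "(" + ",".join(parts) + ");"


def _resolve_tree(params: SimParams,
                  rng: np.random.Generator) -> dendropy.Tree:
    if params.tree is not None:
        if isinstance(params.tree, dendropy.Tree):
            return params.tree
        return dendropy.Tree.get(data=params.tree, schema="newick")
    if params.species_partition is not None:
        labels = sorted(params.species_partition)
    else:
        labels = [f"t{i + 1}" for i in range(params.n_taxa)]
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    return dendropy.Tree.get(data=random_tree(labels, rng), schema="newick")


# ---------------------------------------------------------------------------
# Genome layout and ancestral sequence


@dataclass
class _PcgInfo:
    name: str
    strand: str
    start0: int  # 0-based genome offset of the written-strand slice
    length: int
    incomplete: bool


def _build_layout(params: SimParams, rng: np.random.Generator):
    """Fix segment order and lengths; returns (segments, cr_length).

    A segment is (name, kind, strand, length); spacers have kind None.
    Requested genome lengths far from the baseline scale the coding/rRNA
    blocks proportionally; leftover length is distributed over short
    intergenic spacers.
    """
    f = params.genome_length / _BASELINE_LENGTH
    if 0.95 <= f <= 1.15:
        scale = 1.0
    else:
        # tRNA lengths are fixed, so scale only the scalable blocks
        trna_total = sum(_TRNA_LEN.values())
        scale = max(0.05, (params.genome_length - trna_total)
                    / (_BASELINE_LENGTH - trna_total))
    aa = {g: max(20, round(n * scale)) for g, n in _PCG_AA_CODONS.items()}
    rrna = {g: max(100, round(n * scale)) for g, n in _RRNA_LEN.items()}
    cr_len = max(60, round(int(rng.integers(900, 1021)) * scale))

    seg_core = []
    for name, kind, strand in GENOME_ORDER:
        if kind == PCG:
            inc = name in params.incomplete_stop_genes
            length = 3 * aa[name] + (1 if inc else 3)
        elif kind == TRNA:
            length = _TRNA_LEN[name]
        elif kind == RRNA:
            length = rrna[name]
        else:
            length = cr_len
        seg_core.append((name, kind, strand, length))

    total = sum(s[3] for s in seg_core)
    remaining = params.genome_length - total
    if remaining < 0:
        give_back = min(-remaining, cr_len - 60)
        cr_len -= give_back
        seg_core[-1] = (seg_core[-1][0], seg_core[-1][1], seg_core[-1][2],
                        cr_len)
        remaining += give_back
    if remaining < 0:
        raise ValueError(
            f"genome_length {params.genome_length} too small for the "
            f"37-gene layout (needs >= {total + 60 - cr_len})")

    n_gaps = len(seg_core)
    base, extra = divmod(remaining, n_gaps)
    segments = []
    for k, seg in enumerate(seg_core):
        segments.append(seg)
        gap = base + (1 if k < extra else 0)
        if gap:
            segments.append((None, None, None, gap))
    return segments


def _sense_pi(pi: np.ndarray, strand: str) -> np.ndarray:
    return pi if strand == "H" else pi[_COMPLEMENT_IDX]


def _draw_codon(rng: np.random.Generator, pi: np.ndarray) -> tuple[int, ...]:
    while True:
        c = tuple(int(b) for b in rng.choice(4, size=3, p=pi))
        if c not in (_STOP_TAA, _STOP_TAG):
            return c


def _make_ancestor(params: SimParams, pi: np.ndarray,
                   rng: np.random.Generator):
    """Build the ancestral genome; returns (seq, rates, features, pcg_infos)."""
    segments = _build_layout(params, rng)
    length = sum(s[3] for s in segments)
    seq = np.zeros(length, dtype=np.int8)
    rates = np.ones(length, dtype=float)
    features: list[GeneFeature] = []
    pcg_infos: list[_PcgInfo] = []
    mult = params.rate_multipliers

    pos = 0
    for name, kind, strand, seg_len in segments:
        if kind in (None, TRNA, RRNA, CONTROL_REGION):
            seq[pos:pos + seg_len] = rng.choice(4, size=seg_len, p=pi)
            if kind is not None:
                features.append(GeneFeature.make(
                    name=name, kind=kind, start=pos + 1, end=pos + seg_len,
                    strand=strand))
        else:  # PCG, generated in gene orientation
            spi = _sense_pi(pi, strand)
            incomplete = seg_len % 3 == 1
            n_aa = (seg_len - (1 if incomplete else 3)) // 3
            sense = []
            start_third = int(rng.choice(4, p=spi))
            sense.extend((0, 3, start_third))  # ATN start
            for _ in range(n_aa - 1):
                sense.extend(_draw_codon(rng, spi))
            sense.extend((3,) if incomplete else _STOP_TAA)
            sense_arr = np.array(sense, dtype=np.int8)
            sense_rates = np.array(
                [mult[i % 3] for i in range(seg_len)], dtype=float)
            if strand == "H":
                seq[pos:pos + seg_len] = sense_arr
                rates[pos:pos + seg_len] = sense_rates
            else:
                seq[pos:pos + seg_len] = _COMPLEMENT_IDX[sense_arr][::-1]
                rates[pos:pos + seg_len] = sense_rates[::-1]
            features.append(GeneFeature.make(
                name=name, kind=PCG, start=pos + 1, end=pos + seg_len,
                strand=strand, incomplete_stop=incomplete))
            pcg_infos.append(_PcgInfo(name=name, strand=strand, start0=pos,
                                      length=seg_len, incomplete=incomplete))
        pos += seg_len
    return seq, rates, features, pcg_infos


def _sense_view(seq: np.ndarray, info: _PcgInfo) -> np.ndarray:
    sl = seq[info.start0:info.start0 + info.length]
    return sl if info.strand == "H" else _COMPLEMENT_IDX[sl][::-1]


def _sense_index_to_genome(info: _PcgInfo, i: int) -> int:
    if info.strand == "H":
        return info.start0 + i
    return info.start0 + info.length - 1 - i


# ---------------------------------------------------------------------------
# Evolution


def _evolve_branch(parent: np.ndarray, rates: np.ndarray, Q: np.ndarray,
                   t: float, pcg_infos: list[_PcgInfo],
                   rng: np.random.Generator,
                   rate_classes: dict[float, np.ndarray]) -> np.ndarray:
    child = parent.copy()
    if t <= 0.0:
        return child
    P_by_rate = {r: expm(Q * r * t) for r in rate_classes}
    cum_by_rate = {}
    for r, P in P_by_rate.items():
        cum = P.cumsum(axis=1)
        cum[:, -1] = 1.0  # guard against fp shortfall in the last bin
        cum_by_rate[r] = cum
    for r, idx in rate_classes.items():
        u = rng.random(len(idx))
        rows = cum_by_rate[r][parent[idx]]
        child[idx] = (u[:, None] > rows).sum(axis=1)

    # coding constraints, enforced by rejection-resampling the offending
    # sites (fallback: keep the parent state, which always satisfied them):
    #   * no in-frame internal stop codon
    #   * start codon stays ATN
    #   * terminal stop stays TAA/TAG (or trailing T for incomplete genes)
    def _resample_sense_codon(info, ci, accept):
        gidx = [_sense_index_to_genome(info, 3 * ci + k) for k in range(3)]
        sense_now = _codon_from_genome(child, info, gidx)
        if accept(sense_now):
            return
        for _try in range(50):
            new = np.empty(3, dtype=np.int8)
            for k, g in enumerate(gidx):
                row = cum_by_rate[rates[g]][parent[g]]
                new[k] = int((rng.random() > row).sum())
            cand = (tuple(int(b) for b in new) if info.strand == "H"
                    else tuple(int(b) for b in _COMPLEMENT_IDX[new]))
            if accept(cand):
                for k, g in enumerate(gidx):
                    child[g] = new[k]
                return
        for g in gidx:
            child[g] = parent[g]

    not_stop = lambda c: c not in (_STOP_TAA, _STOP_TAG)
    is_atn = lambda c: c[0] == 0 and c[1] == 3
    is_stop = lambda c: c in (_STOP_TAA, _STOP_TAG)
    for info in pcg_infos:
        n_codons = info.length // 3  # trailing incomplete T not a codon
        _resample_sense_codon(info, 0, is_atn)
        for ci in range(1, n_codons if info.incomplete else n_codons - 1):
            _resample_sense_codon(info, ci, not_stop)
        if info.incomplete:
            g = _sense_index_to_genome(info, info.length - 1)
            want = 3 if info.strand == "H" else _COMPLEMENT_IDX[3]
            if child[g] != want:
                child[g] = parent[g]  # keep the incomplete-stop T
        else:
            _resample_sense_codon(info, n_codons - 1, is_stop)
    return child


def _codon_from_genome(seq: np.ndarray, info: _PcgInfo,
                       gidx: list[int]) -> tuple[int, ...]:
    vals = np.array([seq[g] for g in gidx], dtype=np.int8)
    if info.strand == "L":
        vals = _COMPLEMENT_IDX[vals]
    return tuple(int(b) for b in vals)


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def simulate(params: SimParams) -> tuple[list[MitoRecord], GroundTruth]:
    """Generate annotated mitogenome records for every tree tip.

    Returns the records plus a :class:`GroundTruth` carrying the tree, the
    per-pair path lengths and their expected p-distances (closed form under
    the generating model, averaged over the site-rate mixture), the true
    species labels, and the realized per-record base counts.
    """
    rng = np.random.default_rng(params.seed)
    pi = stationary_frequencies(params.at_target, params.at_skew_target,
                                params.gc_skew_target)
    if any(r <= 0 for r in params.rate_multipliers):
        raise ValueError("rate multipliers must be positive")
    Q = hky_rate_matrix(pi, params.kappa)

    tree = _resolve_tree(params, rng)
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree tip labels are not unique")

    anc_seq, rates, features, pcg_infos = _make_ancestor(params, pi, rng)
    rate_classes = {float(r): np.flatnonzero(rates == r)
                    for r in np.unique(rates)}

    # evolve along the tree, preorder
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): anc_seq}
    tip_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            cur = anc_seq
        else:
            t = node.edge.length or 0.0
            cur = _evolve_branch(seqs[id(node.parent_node)], rates, Q, t,
                                 pcg_infos, rng, rate_classes)
        seqs[id(node)] = cur
        if node.is_leaf():
            tip_seqs[node.taxon.label] = cur

    records = [MitoRecord(id=label, sequence=_decode(tip_seqs[label]),
                          circular=True, features=list(features))
               for label in leaves]

    # ground truth
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    share = {r: len(idx) / len(rates) for r, idx in rate_classes.items()}
    path_length: dict[tuple[str, str], float] = {}
    expected_p: dict[tuple[str, str], float] = {}
    P_cache: dict[tuple[float, float], float] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            d = float(pdm.distance(tns.get_taxon(a), tns.get_taxon(b)))
            key = (a, b) if a <= b else (b, a)
            path_length[key] = d
            p = 0.0
            for r, w in share.items():
                ck = (r, d)
                if ck not in P_cache:
                    P_cache[ck] = float(
                        1.0 - np.dot(pi, np.diag(expm(Q * r * d))))
                p += w * P_cache[ck]
            expected_p[key] = p
    counts = {}
    for rec in records:
        arr = tip_seqs[rec.id]
        counts[rec.id] = {b: int((arr == i).sum())
                          for i, b in enumerate("ACGT")}
    species = (dict(params.species_partition)
               if params.species_partition is not None else None)
    gt = GroundTruth(
        tree_newick=tree.as_string(schema="newick").strip(),
        labels=leaves,
        path_length=path_length,
        expected_p=expected_p,
        species=species,
        base_counts=counts,
        ancestor_sequence=_decode(anc_seq),
        pi=tuple(float(x) for x in pi),
        kappa=params.kappa,
        rate_multipliers=tuple(params.rate_multipliers),
        site_rate_share=share,
    )
    return records, gt
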