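"""PCG12 supermatrix construction and neighbor-joining trees.

``build_pcg12`` concatenates in-frame per-gene alignments in canonical
genome order and keeps a chosen subset of codon positions (positions {1, 2}
by default, the usual remedy for third-position saturation).  ``nj_tree``
is a deterministic Saitou-Nei implementation; ``clade_check`` tests whether
a label set forms one side of an edge bipartition (a clade on some rooting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .io import PCG_NAMES

__all__ = [
    "SuperMatrix",
    "build_pcg12",
    "write_supermatrix_fasta",
    "write_supermatrix_phylip",
    "write_partition_file",
    "nj_tree",
    "clade_check",
]

#: canonical concatenation order = genome order of the 13 PCGs
CANONICAL_GENE_ORDER = tuple(PCG_NAMES)


@dataclass
class SuperMatrix:
    """Concatenated codon-position-filtered alignment plus partition table."""

    labels: list[str]
    per_gene: dict[str, dict[str, str]]  # gene -> label -> filtered block
    concatenated: dict[str, str]  # label -> full row
    positions_kept: tuple[int, ...]
    partition_table: dict[str, tuple[int, int]]  # gene -> 1-based (start, end)

    @property
    def length(self) -> int:
        return len(next(iter(self.concatenated.values()))) if self.labels else 0


def _filter_positions(seq: str, positions: Sequence[int]) -> str:
    keep = sorted(set(positions))
    return "".join(seq[i] for i in range(len(seq)) if (i % 3) + 1 in keep)


def build_pcg12(gene_alignments: Mapping[str, Mapping[str, str]],
                positions: Sequence[int] = (1, 2),
                gene_order: Sequence[str] | None = None) -> SuperMatrix:
    """Concatenate per-gene codon alignments, keeping selected positions.

    ``gene_alignments`` maps gene name -> (label -> aligned in-frame
    sequence); every block must have a length divisible by three and a single
    length across its members.  A taxon missing from a gene gets an all-gap
    block (with a warning), so public records of varying completeness can
    still be combined.
    """
    keep = tuple(sorted(set(positions)))
    if not keep or not set(keep) <= {1, 2, 3}:
        raise ValueError(f"positions must be a non-empty subset of {{1,2,3}}, "
                         f"got {positions}")
    order = [g for g in (gene_order or CANONICAL_GENE_ORDER)
             if g in gene_alignments]
    extra = sorted(set(gene_alignments) - set(order))
    order += extra  # unknown genes appended alphabetically

    labels: list[str] = []
    for g in order:
        for l in gene_alignments[g]:
            if l not in labels:
                labels.append(l)

    per_gene: dict[str, dict[str, str]] = {}
    partition: dict[str, tuple[int, int]] = {}
    concat = {l: [] for l in labels}
    offset = 0
    for g in order:
        block = gene_alignments[g]
        lengths = {len(s) for s in block.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {g!r}: members differ in aligned length")
        (blen,) = lengths
        if blen % 3 != 0:
            raise ValueError(
                f"gene {g!r}: aligned length {blen} not divisible by 3")
        flen = sum(1 for i in range(blen) if (i % 3) + 1 in keep)
        per_gene[g] = {}
        for l in labels:
            if l in block:
                row = _filter_positions(block[l].upper(), keep)
            else:
                warnings.warn(f"taxon {l!r} missing gene {g!r}; padding with "
                              f"gaps", stacklevel=2)
                row = "-" * flen
            per_gene[g][l] = row
            concat[l].append(row)
        partition[g] = (offset + 1, offset + flen)
        offset += flen
    return SuperMatrix(labels=labels, per_gene=per_gene,
                       concatenated={l: "".join(parts)
                                     for l, parts in concat.items()},
                       positions_kept=keep, partition_table=partition)


def write_supermatrix_fasta(sm: SuperMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in sm.labels:
            fh.write(f">{l}\n{sm.concatenated[l]}\n")


def write_supermatrix_phylip(sm: SuperMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: name, whitespace, then the full row."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.labels)} {sm.length}\n")
        for l in sm.labels:
            fh.write(f"{l}  {sm.concatenated[l]}\n")


def write_partition_file(sm: SuperMatrix, path: str | Path) -> None:
    """RAxML-style partition lines: ``DNA, gene = start-end``."""
    with open(path, "w") as fh:
        for g, (s, e) in sm.partition_table.items():
            fh.write(f"DNA, {g} = {s}-{e}\n")


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the label order of the input
    matrix.  Negative branch lengths are clamped to zero with the deficit
    moved onto the sibling branch, so path lengths on the joined pair are
    preserved.  The returned tree is unrooted (trifurcation at the seed
    node for more than three taxa).
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(m.values).any():
        raise ValueError("distance matrix contains undefined entries")

    tns = dendropy.TaxonNamespace(m.labels)
    nodes: list[dendropy.Node] = []
    for label in m.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    # tie-break key: smallest original label index under each node
    keys = list(range(n))
    D = m.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        na = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(na):
            for aj in range(ai + 1, na):
                q = (na - 2) * sub[ai, aj] - r[ai] - r[aj]
                i, j = active[ai], active[aj]
                ki, kj = sorted((keys[i], keys[j]))
                cand = (q, ki, kj, ai, aj)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj

        # new row: d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2
        new_idx = D.shape[0]
        newrow = np.zeros(new_idx + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, :new_idx] = newrow[:new_idx]
        D[:new_idx, new_idx] = newrow[:new_idx]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def clade_check(tree: dendropy.Tree, group: Iterable[str]) -> bool:
    """True iff ``group`` forms one side of an edge bipartition of ``tree``."""
    want = frozenset(group)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = want - tips
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(want) in (1, len(tips)):
        return True
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(leaf.taxon.label
                          for leaf in node.leaf_iter())
        if below == want or tips - below == want:
            return True
    return False
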