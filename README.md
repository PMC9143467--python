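# mitocomp

Comparative mitochondrial-genome analysis for small taxon sets, built around
the workflow used to detect cryptic species from whole-mitogenome data:

- **I/O** — annotated mitogenome records from GenBank flat files or
  FASTA + TSV feature tables, with gene-name normalization to the canonical
  37-gene insect vocabulary (`mitocomp.io`).
- **Composition** — per-region base composition, A+T content, and AT/GC
  strand skew (`(A−T)/(A+T)`, `(G−C)/(G+C)`), computed on gene-oriented
  sequences per strand class (`mitocomp.composition`).
- **Codon usage** — codon counts, RSCU, translation, and start/stop-codon
  classification (including incomplete `T`/`TA` stops) under the
  invertebrate mitochondrial genetic code (`mitocomp.codons`).
- **Distances & delimitation** — p-distance and K2P on aligned sequences
  with pairwise deletion, labelled distance matrices, and single-linkage
  species delimitation at a conspecific threshold with cryptic-candidate
  flagging from morphospecies labels (`mitocomp.distances`). A published
  6-taxon Vietnamellidae whole-mitogenome distance matrix ships as a
  fixture (`load_vietnamellidae_distances`).
- **Supermatrices & trees** — PCG12 construction (concatenate the 13
  protein-coding genes, keep codon positions 1+2), partition tables,
  relaxed-PHYLIP/FASTA writers, a deterministic neighbor-joining
  implementation, and clade checks (`mitocomp.supermatrix`).
- **Simulation** — seeded generator of annotated ~15.6 kb circular
  mitogenomes with the canonical gene order, target A+T content and strand
  skews, HKY evolution along a tree with per-codon-position rates, coding
  constraints, and full ground truth (`mitocomp.simulate`).

## CLI

Every stage is a subcommand of `mitocomp` with one input → output contract;
runs write a `runconfig.json` next to their outputs.

```sh
mitocomp simulate --n-taxa 6 --seed 1 --out sim/        # records + ground truth
mitocomp stats sim/records.gb                           # composition / skew TSV
mitocomp rscu sim/records.gb                            # codon usage TSV
mitocomp codons sim/records.gb                          # start/stop report
mitocomp distance aln.fasta --model p --out dist/       # distance matrix
mitocomp delimit --matrix dist/distances.tsv --t-intra 0.07 \
    --morphospecies morpho.tsv --out delim/             # delimitation report
mitocomp pcg12 genes/*.fasta --positions 12 --out sm/   # PCG12 supermatrix
mitocomp njtree --matrix dist/distances.tsv --out tree.nwk
```

`--model {p,k2p}` selects the distance model; `--t-intra` is the
conspecific threshold (default 0.07, the upper end of typical insect
intraspecific divergence); `--positions 12|123` selects codon positions.

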