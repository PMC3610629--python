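# chromosteer

Coarse-grained chromosome polymer simulation with expression-derived
colocalization restraints and spatial macrodomain analysis.

The package implements an end-to-end strategy for asking whether coregulated
gene pairs on a chromosome can be brought simultaneously into spatial
proximity:

1. **`synthetic`** — expression compendia with planted clique-structured
   coregulation, gene annotations, and block-structured reference contact
   maps, so the whole pipeline is testable without external downloads.
2. **`network`** — coregulation network inference: tertile discretization,
   plug-in mutual information (bits), a two-parameter gamma null fitted per
   genomic-distance bin (truncated maximum likelihood on the histogram
   bulk), E-value thresholds (expected false positives = 1 per bin),
   Kuhn-length redundancy filtering, clustering coefficients, and
   degree-preserving / position-randomizing null models.
3. **`polymer`** — bead-spring chains (FENE bonds, Kratky-Porod bending,
   WCA excluded volume on all pairs, intra- and inter-chain) in a periodic
   cubic box; constructors for mitotic-like solenoids, random walks
   (optionally confined), and non-overlapping multi-chain placement.
4. **`engine`** — Langevin dynamics (BAOAB; reduces to velocity Verlet at
   zero friction), numba cell-list force kernels, force-capped push-off
   relaxation, and the contact-probability P(s) diagnostic.
5. **`steering`** — gene-to-bead footprints, per-copy harmonic
   center-of-mass restraints with a linear stiffness ramp, and the
   colocalization order parameter Q (percent of pairs within the contact
   cutoff).
6. **`domains`** — binary 60-kb contact maps from conformations or
   enrichment lists, exact dynamic-programming segmentation into contiguous
   macrodomains (centromere fixed as one domain), and partition comparison
   with maximal one-to-one overlap plus a permutation p-value.
7. **`cli_io`** (`io`, `pipeline`, `cli`) — plain-text formats (TSV, BED,
   dense/triplet maps, extended XYZ), a reproducible pipeline driver, and a
   click CLI.

Internally the simulation uses reduced units (bead diameter sigma = 1,
kT = 1, mass = 1); the default calibration is 30 nm and 10 kb per bead with
a 150 nm persistence length.

## CLI

```sh
chromosteer simulate-expression --n-cliques 6 --seed 1 --out-prefix syn
chromosteer infer-network --expression syn.expression.tsv --annotation syn.genes.bed --out net.tsv
chromosteer build-system --n-chains 2 --n-beads 300 --out system.xyz
chromosteer relax --system system.xyz --out relaxed.xyz
chromosteer steer --system relaxed.xyz --net net.tsv --ann syn.genes.bed --steps 10000
chromosteer contact-map --triplets hic.tsv --threshold 1.5 --n-segments 50
chromosteer segment --map map.txt --n-domains 8 --centromere 22 27
chromosteer compare-partitions --map-a a.txt --map-b b.txt --n-domains 8
chromosteer pipeline --seed 1 --out-dir pipeline_out
```

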