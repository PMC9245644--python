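# repeatscape

Comparative repeatome analysis as a reusable, tested pipeline:

- **io_formats** — readers/writers for RepeatMasker `.out` tables, GFF3 gene
  annotations, repeat-library FASTA (`Name#Class/Family` headers), genome
  indexes and Newick trees. All coordinates are 0-based half-open internally;
  1-based inclusive formats are converted at the boundary.
- **clustering** — greedy centroid clustering of repeat consensus sequences
  at a fixed identity threshold (default 0.80), with an exact
  Needleman–Wunsch identity (matching columns / alignment columns) and a
  disableable k-mer prefilter.
- **quantify** — per-genome occupancy matrices by repeat class or cluster
  (merged base pairs as proportions of assembly size, union-based totals) and
  100-kb windowed density tracks.
- **ordination** — PCA of genomes in repeat space (scores, biplot-ready
  loadings, variance explained, deterministic sign convention) and
  rank-abundance distributions of repeat clusters with cross-genome rank
  tables.
- **enrichment** — resampling-based tests for repeat enrichment in gene-set
  flank regions: pooled density statistic, one-sided add-one empirical
  p-values (floor 1/(N+1), i.e. 0.002 at N = 499), fold enrichment vs the
  null mean, and Benjamini–Hochberg FDR across categories with shared null
  draws.
- **pgls** — phylogenetic generalized least squares under a Brownian-motion
  covariance, solved by Cholesky factorization (star tree ≡ OLS).
- **synthetic** — seed-deterministic generators: repeat libraries, genomes
  with planted repeat landscapes and planted regional enrichments (truth
  records store planted *and* realized quantities), random ultrametric trees
  and Brownian trait simulation.
- **pipeline / cli** — subcommand orchestration and a one-shot `full-run`.

## CLI

```sh
repeatscape simulate --config sim.yaml --outdir fixtures/
repeatscape cluster  --library fixtures/library.fasta --identity 0.8 --out clusters.tsv
repeatscape quantify --hits fixtures/sim.out --index fixtures/sim.fai --by class --out occ.tsv
repeatscape windows  --hits fixtures/sim.out --index fixtures/sim.fai --window 100000 --out win.bed
repeatscape ordinate --matrix occ.tsv --outdir pca/
repeatscape rad      --matrix occ_cluster.tsv --top 100 --out rad.tsv
repeatscape enrich   --hits fixtures/sim.out --genes fixtures/sim.gff3 \
    --index fixtures/sim.fai --focal focal.txt \
    --classes LINE/BovB,DNA/TcMar-Tc1,total \
    --flank 1000 --resamples 499 --fdr 0.1 --seed 1 --out enrich.tsv
repeatscape pgls     --tree tree.nwk --traits traits.tsv --out pgls.json
repeatscape full-run --config run.yaml --outdir results/
```

A `simulate` config is a YAML document mirroring `SimulationConfig`
(see `repeatscape.synthetic`); a `full-run` config lists per-genome input
paths plus parameter blocks (clustering, enrichment, window size, PGLS trait
columns) and a global seed. Reruns with identical config + seed produce
byte-identical outputs.

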