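# cypfam

Genome-wide cytochrome P450 (CYP) family analysis for fungal genomes:
motif-based authentication of P450 proteins, a species × family census with a
fractional enrichment cutoff, minimum-evolution phylogenetics, exon–intron
gene-structure comparison for paralog/ortholog calling, tandem-array
detection, and a seeded synthetic-genome generator with planted ground truth.

## The problem

Wood-decaying basidiomycete fungi carry unusually large P450 complements
(one to several hundred genes per genome). When one CYP family holds far
more members than the rest, that expansion is a signature of selection —
typically driven by local (tandem) gene duplication. `cypfam` implements the
comparative workflow that turns a set of annotated genomes into those calls:

1. **Authentication.** A candidate protein is an authentic P450 only if it
   carries both signature motifs — the heme-binding decapeptide
   `FXXGXXXCXG` (the C is the axial cysteine ligand of the heme iron) and
   the K-helix salt bridge `EXXR` — with at least one `EXXR` start strictly
   upstream of a heme-motif start, as in every P450 fold. Positions marked
   `X` in a pattern accept any of the 20 standard residues but not the
   ambiguity code `X`. Sequences failing either condition (pseudogenes,
   truncated models) are rejected with machine-readable reasons.
2. **Census and enrichment.** Authentic P450s are counted per species and
   family (`CYP<family><subfamily><member>` nomenclature). A family is
   *enriched* when its summed count reaches a fraction *f* (default 2%) of
   all counted P450s: the cutoff is round-half-up(*f* · total), so a total
   of 1061 P450s gives a cutoff of 21 members. Enriched families present in
   at most *k* species (default 2) are flagged species-specific.
3. **Minimum-evolution phylogenetics.** Per enriched family:
   p-distances from the alignment (complete deletion by default) →
   Poisson correction *d* = −ln(1 − *p*) (amino-acid substitutions per
   site) → neighbor-joining start tree → ordinary-least-squares branch
   lengths on the fixed topology → close-neighbor-interchange (CNI) search
   that accepts a nearest-neighbor-interchange (NNI) neighbor only when it
   strictly lowers the ME score Σ branch lengths. An exhaustive enumerator
   over all unrooted binary topologies (≤ 8 taxa) serves as an independent
   optimum oracle.
4. **Gene structure.** Exon–intron structures (strand-normalised exon-length
   vectors from GFF3 gene models) are compared by exon-count-gated
   positional matching with a ±3 nt tolerance; single-linkage clusters of
   same-structure genes within a species are duplicate (paralog) groups,
   cross-species matches are ortholog candidates, and per family × species
   the intron counts of proteins ≥ 400 aa are summarised as min–max and the
   modal P/I statistic (P genes sharing I introns).
5. **Tandem arrays.** Two or more same-family genes co-located on one
   scaffold form a tandem array (strand ignored; an optional stricter rule
   caps intervening non-family genes).

Because the underlying genome portals and supplementary tables are not
machine-readable, the package ships a first-class synthetic-data module
(`cypfam.synth`) that emits FASTA + GFF3 + name tables with planted counts,
duplications, orthologs, tandem placements and pseudogenes, plus the truth
labels needed to verify every stage end to end.

## Worked example

```bash
cypfam simulate --seed 11 --out-dir demo
# 347 genes (35 pseudogenes) -> demo/proteins.fasta, demo/genes.gff3, demo/names.tsv, demo/truth.json

cypfam run-all demo/proteins.fasta --gff3 demo/genes.gff3 \
       --tree-max-taxa 20 --out-dir demo/report
# census total 312, cutoff 6, enriched: CYP5144, CYP512, CYP5150, CYP5035, CYP5348, CYP5359
```

The simulated complement plants 347 genes across six species and twelve
families; 35 (10%) have ablated motifs and are rejected at authentication,
leaving a census of 312. Two percent of 312 rounds to a cutoff of 6, and the
six large planted families clear it while the six rare ones do not.
`demo/report/` then contains, among others:

`enriched_matrix.tsv` — the species × enriched-family count matrix:

```text
species  CYP5144  CYP512  CYP5150  CYP5035  CYP5348  CYP5359
Abis     13       10      5        0        0        0
Gsp      2        19      20       10       3        14
Pcar     41       14      8        12       0        0
...
```

`intron_summary.tsv` — per family × species intron profiles (`NA` where no
member protein reaches 400 aa; `13/10` means 13 genes share the modal count
of 10 introns — conserved structure, the signature of duplication):

```text
family   species  n_genes  n_qualifying  min_max_introns  P_over_I
CYP512   Abis     10       0             NA               NA
CYP5144  Abis     13       13            10               13/10
CYP5150  Abis     5        5             6                5/6
```

`tandem_arrays.tsv` — same-family genes sharing a scaffold:

```text
family   species  scaffold          size  members
CYP512   Abis     Abis_scaffold001  10    Abis_0002,Abis_0003,...
```

`trees/CYP5359.nwk` — the minimum-evolution tree of each (sufficiently
small, per `--tree-max-taxa`) enriched family, with OLS branch lengths in
substitutions per site:

```text
(Gsp_0062:0.0194615,(((((Gsp_0063:0.0308439,Gsp_0072:0.0196255):0.000496556,...
```

Every stage is also available as a library call (`cypfam.scan_motifs`,
`cypfam.build_census`, `cypfam.enrich`, `cypfam.family_tree`,
`cypfam.cluster_paralogs`, `cypfam.detect_tandem`, ...) and as an individual
subcommand (`authenticate`, `census`, `enrich`, `tree`, `simulate`,
`run-all`).

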