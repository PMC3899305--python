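# Methods

This note documents the models and procedures `cypfam` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signature-motif authentication

A candidate protein is called an authentic P450 when it contains both
signature motifs with the K-helix upstream of the heme ligand:

- heme-binding decapeptide `FXXGXXXCXG`: F at offset 0, G at 3, C at 7
  (the axial cysteine), G at 9, any standard residue elsewhere;
- K-helix tetrapeptide `EXXR`: E at offset 0, R at 3.

All (possibly overlapping) matches are reported; the protein is authentic
iff both lists are non-empty and min(EXXR starts) < max(heme starts).

Decisions taken where the motif definition is under-specified:

- **Ambiguity code `X`.** Pattern wildcards accept the 20 standard
  residues only — an unknown residue cannot positively evidence a motif.
- **Order and multiplicity.** At least one `EXXR` must start strictly
  before at least one heme match; multiple matches are allowed. The
  K-helix precedes the heme ligand in all known P450 folds, so demanding
  the order costs nothing on real P450s and rejects spurious single-motif
  hits.
- **Normalisation.** Sequences are uppercased and a single trailing `*`
  stop is stripped on ingest; any other non-standard character rejects the
  record as `bad-sequence`.
- **No length filter at authentication.** The ≥ 400 aa floor applies only
  to intron summaries (see below), not to authentication.
- When *both* motifs are missing the single reported reason is
  `missing-heme`, the defining P450 signature.

## Census and enrichment

CYP names parse as `CYP` + family integer + optional subfamily letter +
optional member integer (prefix case-insensitive). The census is keyed by
family only; species rows sort lexicographically and family columns by
family number, so the table is a deterministic function of the record set.
Unparseable names abort the census listing every offender — silent drops
would corrupt the totals downstream.

The enrichment cutoff is round-half-up(fraction × total), fraction 0.02 by
default. Rounding direction is a convention: half-up yields 21 for
0.02 × 1061 = 21.22 and is stable in the direction users expect when the
product lands on .5. A family is enriched iff its summed count ≥ cutoff;
"species-specific" means an enriched family present in ≤ k species
(default k = 2, configurable) — a numeric reading of single- or two-genome
expansions.

## Minimum-evolution phylogenetics

Input is a protein alignment (alignment construction is out of scope;
aligned FASTA is accepted per family, and the generator's substitution-only
sequences are their own alignment).

- **p-distance.** Proportion of differing residues among compared
  columns. *Complete deletion* (default, the common default in
  distance-based protein phylogenetics) removes every column gapped in any
  taxon before any pair is compared; *pairwise deletion* drops gapped
  columns per pair. Zero comparable columns is an error.
- **Poisson correction.** d = −ln(1 − p), amino-acid substitutions per
  site. p ≥ 1 has no correction and errors at the function level; the
  matrix builder treats p > 0.95 as saturated, warns, and caps the
  distance at −ln(0.05) ≈ 3.0 so matrices stay finite without silently
  distorting typical inputs.
- **Neighbor joining.** Standard Saitou–Nei agglomeration on the
  Q-criterion. Ties are broken by the smallest (i, j) pair in the current
  working order; n = 2 yields a single edge, n = 3 the closed-form star.
  Both conventions are fixed so runs are bit-reproducible.
- **OLS branch lengths.** On a fixed unrooted binary topology the lengths
  minimise Σ over pairs (d_ij − path_ij)²; solved with a dense
  least-squares system over the 2n − 3 path-incidence columns. Negative
  fitted lengths are *kept* in the ME score (the criterion is the raw sum
  of branches) and clamped to zero only in the emitted Newick — scoring
  and presentation serve different contracts.
- **CNI search.** Iterated best-improvement local search. Search level 1
  (the default) explores the 2(n − 3) topologies one NNI away; level k
  expands to topologies within k NNI moves. A neighbor is accepted only
  when its ME score improves by more than 1e−12, so the result never
  scores worse than its start and terminates at an NNI-local optimum.
  Level 1 is interpreted as the single-NNI neighborhood; coarser
  tree-search software does not document its exact level semantics, so
  topological agreement with any particular external implementation is not
  claimed.
- **Exhaustive oracle.** All (2n − 5)!! unrooted binary topologies are
  enumerated by sequential leaf insertion (n ≤ 8, 10 395 topologies),
  each fitted by OLS; ties on the ME score break toward the
  lexicographically smallest Newick. Topology banks and enumeration order
  are cached per taxon set.
- **Newick.** The unrooted tree is written as a basal trifurcation at the
  internal node adjacent to the alphabetically first taxon, siblings
  ordered by smallest contained taxon — a canonical string per topology.

## Gene structure

Gene models come from GFF3 (1-based inclusive) and are stored 0-based
half-open. Profiles are computed from CDS features when present, else exon
features, never mixing the two — this removes UTR ambiguity
deterministically. Profiles are strand-normalised: minus-strand exon order
is reversed, so a profile is invariant under coordinate mirroring plus
strand flip. As an internal consistency check (replacing external
mRNA-to-genome alignment), the summed CDS length is compared with
3 × protein length + 3 when both are known; mismatches warn rather than
fail because annotated gene models are imperfect.

Structural similarity is exon-count-gated positional length matching:
profiles with different intron counts score 0; otherwise the score is the
fraction of positionally paired exons with |Δlength| ≤ tol_nt. Defaults
tol_nt = 3 (one codon — the smallest tolerance that survives
codon-boundary annotation wobble) and θ = 0.8 for the same-structure call;
both configurable. Paralog groups are single-linkage components of
same-structure edges within one species + family; ortholog candidates are
cross-species same-structure pairs (many-to-one allowed: one gene may
match a whole duplicate cluster in another species).

Intron summaries count only genes whose protein is ≥ 400 aa (short models
make intron counts incomparable). Reported are min–max intron counts and
P/I — the number of genes P sharing the modal intron count I. All tied
modes are listed (descending I); the canonical mode breaks ties toward the
smaller intron count. No qualifying gene yields an explicit NA summary.

## Tandem arrays

The default criterion is scaffold co-location: ≥ 2 same-species,
same-family genes on one scaffold form one array, members ordered by start
coordinate — faithfulness to the scaffold-level reading first. A stricter
optional rule (`max_intervening`) splits a group wherever more than that
many non-family genes lie between consecutive members. Strand is ignored.
Scaffold distributions list per-scaffold member counts including
singletons, sorted by descending count then scaffold name.

## Synthetic data generator

`cypfam.synth.generate` emulates a six-genome comparative input: for each
family an ancestral protein (length drawn per family; motifs planted with
`EXXR` near 70% and the heme decapeptide near 90% of the length, positions
jittered ±5 residues, matching real P450 architecture) and an ancestral
exon structure (5–18 exons, ≥ 30 nt each, total 3L + 3 nt). With
probability `ortholog_fraction` (default 0.5) a multi-species family is
seeded before the species split: founders in each species diverge from the
common ancestor at `mu_speciation` (default 0.15 substitutions/site) with
structure conserved, and founder pairs are recorded as orthologs;
otherwise each species founder is drawn independently. Within a species,
counts are filled by duplication events: each copy diverges from its
lineage *founder* at `mu_duplication` (default 0.03), copies the founder's
exon structure exactly (or with one boundary moved by ≤
`structural_jitter_nt`, default 0), and lands on the parent scaffold with
probability `p_tandem` (default 0.7, downstream with 2 kb intergenic
spacing) else on a fresh scaffold.

Divergence is substitution-only (probability 1 − e^(−μ) per site, to a
uniformly chosen different residue; motif windows protected), so expected
parent–child p-distance equals 1 − e^(−μ) exactly and ungapped family
alignments are valid phylogenetic input. Duplicates diverge from the
founder rather than chained copy-of-copy so sequence and structural
deviation stay bounded by the per-event parameters.

Pseudogenes: round-half-up(`pseudo_fraction` × N) of the N planted genes
(default 10%) are apportioned across families by largest remainder —
deterministic, near-proportional, and guaranteeing that the planted
enriched/rare margins survive ablation — and their motifs are destroyed
(heme cysteine and/or EXXR anchors mutated, rescanning until
authentication fails, so chance background motifs cannot resurrect a
pseudogene). The truth census, enrichment calls, paralog clusters,
ortholog pairs and tandem arrays all describe the authentic genes only.

The default configuration plants 347 genes in twelve families across six
species: six expanded families (two of them confined to ≤ 2 species) whose
authentic totals clear the 2% cutoff by ≥ 5 members, and six singleton
families that stay ≥ 5 below it, so rounding can never flip a call. What
the generator does **not** emulate: indels and alignment uncertainty,
nucleotide-level or codon evolution, rate heterogeneity across sites or
lineages, gene loss/conversion, assembly artefacts, or annotation errors.
Passing recovery tests therefore demonstrate correctness of the analysis
logic under the stated model, not robustness to misalignment or
misannotation in real genomes.

## Numerical choices and problem sizes

- ME-score comparisons use an absolute tolerance of 1e−12 (CNI acceptance
  and tie detection); OLS uses `numpy.linalg.lstsq` with default rcond.
- Distance matrices must be symmetric, finite, non-negative with zero
  diagonal; violations are errors, not warnings.
- Verification problem sizes: neighbor joining is checked on 200 random
  additive matrices with 4–10 taxa; the CNI search against the exhaustive
  oracle on 100 additive and 100 noise-perturbed matrices with 4–7 taxa
  (where full enumeration is cheap); synthetic recovery on 20 seeded
  datasets of ~350 genes each. These sizes make every oracle exact while
  keeping the whole verification suite fast on a single CPU; the
  per-family tree stage in the pipeline accepts a `tree_max_taxa` cap for
  the same reason (OLS refits grow quadratically in pairs per NNI
  neighbor).

## Known limitations

- Family assignment relies on supplied CYP names; no similarity-based
  classification of unnamed sequences is attempted.
- No bootstrap support values, likelihood or Bayesian inference, and no
  alignment construction.
- The CNI neighborhood at level 1 is the NNI set; deeper levels are
  supported but cost grows combinatorially.
- The duplicate-group counts published for real genomes mix tandem and
  structural evidence in ways that are not fully specified; `cypfam`
  reports structural clusters and scaffold distributions separately and
  does not claim to reproduce any particular published per-genome count.
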