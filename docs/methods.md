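# Methods

## Scope and model

`vitacap` treats microbial vitamin biosynthesis as a presence/absence rule
system over KEGG orthologies (KOs), layered on top of standard
relative-abundance ecology.  Three ideas carry the package:

1. **Functional roles and indispensable-role variants.**  KOs that perform
   the same reaction step form a *functional role*; a *pathway variant* is
   one alternative route to a vitamin, defined by an ordered role list and
   the subset of roles that are indispensable.  A genome is a de novo
   producer of a vitamin iff, for some variant, every indispensable role
   has at least one of its KOs in the genome's annotation.  This is a
   deliberately monotone rule: adding annotations can only add producer
   verdicts, which makes annotation dropout (incomplete genomes, missed
   gene calls) strictly conservative.

2. **Cobalamin branch structure.**  The corrin-ring can be built
   anaerobically (cobalt-early, `cbi` genes) or aerobically (cobalt-late,
   `cob` genes); both converge on cob(II)yrinate a,c-diamide, after which
   a shared post-cobyrinate segment (MMAB, cobQ, cbiB, cobP, cobS)
   completes adenosylcobalamin.  A variant tagged `post_cobyrinate` is
   therefore never sufficient alone: the producer rule for cobalamin is
   (anaerobic OR aerobic segment satisfied) AND (post-cobyrinate segment
   satisfied), and the satisfied route is reported under the early
   segment's tag.  The same decomposition drives the complete/partial/
   absent typology (CCG/PCG-style) and the community complementarity
   report, which asks whether the *union* of several partial genomes
   covers a complete route and otherwise names the bottleneck roles.

3. **TPM-sum abundance aggregation.**  Gene counts are converted to TPM
   (length-normalized rates rescaled to a per-sample total of 10^6) with
   the denominator over the entire gene catalog; KO abundance is the TPM
   sum of its genes, role abundance the sum over the role's KOs, pathway
   abundance the sum over the vitamin's KO universe (each KO once, even if
   several variants reference it), and taxon attribution redistributes a
   vitamin's gene TPM over phylum or genus labels with an explicit
   `unassigned` bucket.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_completeness` | 90 | % | strict `>`: boundary genomes rejected |
| `max_contamination` | 5 | % | strict `<` |
| core-KO prevalence | 0.9 | fraction | strict `>` ("more than 90%") |
| rank-sum alpha | 0.05 | — | raw p by default; BH adjustment optional |
| LDA threshold | 3 | log10 units | significance requires \|score\| > 3 AND screen p < alpha |
| AMOVA permutations | 1000 | — | add-one estimator, p resolution 1/1001 |
| TPM total | 10^6 | — | per-sample column sum |

Corrected genome size is `assembly_size × (100/completeness) ×
(1 − contamination/100)`: the assembly is inflated to its expected
complete size and the estimated contaminant fraction removed.  The
"exclusive core KO" comparison between producer and non-producer sets
defaults to the strict reading — core among producers AND absent from
every non-producer genome — with a relaxed option (not core among
non-producers) behind a flag.

## Statistical layer

- **Rank-sum test**: two-sided; exact enumeration when n+m ≤ 12 and the
  pooled sample is tie-free, otherwise the normal approximation with
  midranks, tie correction and continuity correction (delegated to
  `scipy.stats.mannwhitneyu`; the test suite checks the exact branch
  against an independent enumeration oracle for all tie-free 2 ≤ n,m ≤ 5
  configurations).
- **AMOVA**: Excoffier-style squared-distance decomposition,
  `SS_total = Σ_{i<j} d²_ij / N`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
  `Fs = (SS_among/(k−1)) / (SS_within/(N−k))`.  Significance by random
  label permutation with the add-one estimator; an exhaustive mode (two
  groups) enumerates every distinct labeling and reports the plain
  fraction with `Fs* ≥ Fs`, which includes the observed labeling.
  Permutations are vectorised as quadratic forms over group-indicator
  matrices, so a 1000-permutation test on 20 samples costs ~3 ms.
- **PCoA**: classical scaling (double-centering of −D²/2, symmetric
  eigendecomposition, coordinates scaled by √eigenvalue).  Negative
  eigenvalues from non-Euclidean dissimilarities are dropped without
  Lingoes/Cailliez correction and their summed magnitude is reported; a
  cross-check test confirms agreement with `skbio.stats.ordination.pcoa`
  on Euclidean inputs.
- **Bray-Curtis**: `scipy` pairwise distances; a pair of all-zero samples
  is defined to have distance 0 (identical emptiness) rather than NaN.
- **LDA effect size (LEfSe-style)**: features screened per-feature by the
  rank-sum test; samples rescaled to a common 10^6 total (the [1, 10^6]
  abundance axis); 30 bootstrap rounds on 2/3 subsamples of each group fit
  a one-dimensional linear discriminant (`sklearn`); each feature's effect
  is the mean of its raw between-class mean difference and its weighted
  contribution along the discriminant; the score is
  sign · log10(1 + mean effect).  Constant features score 0 and are never
  significant.  Because the inputs are compositions, a very large planted
  change in one feature necessarily perturbs the scaled values of the
  others; scores of untouched features are therefore not exactly zero —
  this mirrors how the procedure behaves on real relative abundances.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

- `make_kb` builds structurally faithful knowledge bases (cobalamin always
  tri-segmented, utilization lists always present and disjoint from
  biosynthesis KOs); all tests of rule-engine correctness run against
  these, never against the curated default KB.
- `simulate_genomes` plants per-vitamin producer fractions exactly
  (`round(f × n)` genomes per vitamin).  Producers receive every KO of the
  indispensable roles of one randomly chosen route; non-producers receive
  a random subset constructed so that at least one indispensable role of
  *every* variant is fully absent, so planted truth is never ambiguous.
  Annotation dropout then removes each KO independently with probability
  `d`; with a single all-indispensable variant the analytic producer
  survival is Π_roles (1 − d^{k_r}) for roles with k_r KOs, and observed
  recall is verified to track it.
- `simulate_community` derives a gene catalog from the genomes (one gene
  per genome × KB-known KO, plus 100 unannotated background genes per
  genome; lengths uniform on [300, 3000] bp; taxonomy inherited from the
  genome).  Each genome has a log-normal base abundance; group-specific
  per-base rates multiply a vitamin gene's rate by the planted fold
  change.  Background genes carry 30× the per-base rate of vitamin genes,
  which keeps vitamin pathways at ~1% of each sample — as in a
  whole-metagenome catalog, where vitamin genes are a small minority and
  the TPM denominator is dominated by everything else.  Per sample,
  genome abundances get group-independent log-normal jitter (sd 0.3,
  emulating biological compositional variability while keeping the null
  exchangeable) and a fixed sequencing depth is drawn multinomially
  (fixed depth keeps TPM denominators stable; Poisson would not).
  Analytic expected pathway TPM and taxon shares are recorded in the
  truth object.
- Presets: `diet` (CON vs HG, 12 samples each, depth 10^6, cobalamin fold
  0.5, most other vitamins 1.4–1.6, pyridoxine 1.0) and `region` (ten GIT
  regions, 5 samples each, depth 10^5, thiamine/niacin/pyridoxine doubled
  in the large intestine).  Both simulate 60 genomes with producer
  fractions between 0.10 and 0.30 per vitamin (cobalamin 0.15), chosen so
  that every pathway is present but producers remain a minority, as in
  real gut genome collections.

What the generator does **not** emulate: phylogenetic correlation of gene
content (capabilities are planted independently per vitamin), read-level
errors and mapping ambiguity (counts are drawn directly), strain-level
variation, and compositional interactions beyond the shared multinomial
denominator.  Passing tests therefore demonstrate correctness of the
rules, aggregation arithmetic and statistical procedures under the stated
noise model — not robustness to annotation bias or mapping artefacts in
real data.

## Numerical and design choices

- Strict inequalities wherever a threshold is phrased as "more than" /
  "greater than" (quality filter, core prevalence); boundary cases are
  excluded by construction and tested.
- All-zero sample columns yield all-zero TPM columns (partial runs are
  common); all-zero abundance rows give richness 0 and Shannon 0.
- Unknown KOs in genome annotations are ignored (whole-genome annotation
  far exceeds the KB universe).
- A gene's TPM contributes fully to its single annotated KO; the input
  dialect carries one KO per gene row.
- Serialization sorts every set before writing, so outputs are
  byte-stable across processes regardless of hash randomization; the
  determinism test compares pipeline outputs byte-for-byte across re-runs.
- Validation problem sizes (1000 oracle pairs, 200 planted genomes, 1000
  AMOVA null replicates at 1000 permutations, 40 diet-contrast seeds, 50
  LDA seeds) were chosen to give tight Monte-Carlo intervals — e.g. the
  AMOVA type-I band [0.03, 0.07] is ±3 binomial SDs around 0.05 at 1000
  replicates — while the whole suite stays comfortably interactive.

## Default knowledge base

`data/default_kb.json` curates the nine vitamins' pathways with every
branch named above (82 roles, 19 variants).  KO ids are filled in where
the gene-symbol → KO mapping is standard (e.g. thiH → K03150, cysG →
K02302, metH → K00548); where it is not, the gene symbol itself is kept as
a first-class alias token (e.g. `bioZ`, `cobG`, `cbrT`) that matches
verbatim against annotations.  The file validates against
`data/kb.schema.json` and is versioned (`vitacap-default-1.0`); users with
their own curation (different KEGG release, added branches) should ship
their own config — everything downstream is KB-agnostic.

## Known limitations

- The curated KB is a best-effort reading of the pathway literature, not
  an authoritative KEGG export; producer calls on real genomes inherit its
  choices (most sensitively, which roles are indispensable).
- The LDA effect size follows the LEfSe convention but is not a
  line-by-line reimplementation of any particular tool; scores agree in
  scale (log10 on a per-million axis) and in the |score| > 3 screening
  behaviour.
- Exhaustive AMOVA is implemented for two groups only; multi-group
  designs use random permutations.
- No rarefaction, compositional (CLR-type) transforms, or multi-group
  (>2) LDA.
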