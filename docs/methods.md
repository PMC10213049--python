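# Methods

`straindyad` infers mother-to-infant transmission of bacterial strains (the
motivating system is *Bifidobacterium* in mother-infant dyad cohorts) by
combining three evidence streams that practitioners usually obtain from
separate tools — whole-genome comparison of cultured isolates, marker-tree
phylogenetic distances, and metagenomic read-pileup comparison — and scores
the integrated calls against a synthetic cohort with known ground truth.
This note records the models, the parameters that matter, and the places
where a genuinely open design choice was made.

## The three evidence streams

**Isolate (culture-genome) rule.** For a mother-infant isolate pair of one
species: transmission requires ANI ≥ 99.9% (the same-strain-lineage
threshold; 98% delimits species), a core-genome SNP distance strictly below
200 (observed transmitted pairs sit at 3–61 SNPs), and the dyad's
same-lineage isolates forming a monophyletic group on the midpoint-rooted
species tree. The SNP cutoff is applied to the post-masking distance; the
unmasked distance is recorded alongside, since which of the two the
original protocol used is ambiguous.

**nPD (marker-tree) rule.** The normalized phylogenetic distance between
two leaves is their patristic distance divided by the tree's total branch
length, making it invariant to branch-length scaling and to rooting. Two
samples share a strain when the minimum nPD over their leaf pairs is
strictly below 0.001 — the calibration point at which isolate-confirmed
identical strains separate from distinct lineages (a 0.01 cutoff is known
to overcount and is not offered as a default). Total branch length sums
the edges of the unrooted tree; the midpoint root splits one edge in two
and leaves both the numerator and denominator unchanged.

**popANI (read-pileup) rule.** Reads from two samples are piled onto one
species reference. A site covered ≥ 5× in both samples is *divergent* only
when the samples' detected allele sets (alleles at ≥ 5% frequency with ≥ 2
reads — published inStrain defaults) are disjoint; sharing even a minor
allele keeps the site non-divergent, which is what distinguishes
population-ANI from consensus ANI. Sharing requires popANI ≥ 99.999%
(compared unrounded) and coverage breadth strictly over 50% in both
samples. The pipeline additionally requires at least 0.1% of the genome
jointly compared before a share call: with only a few dozen jointly
≥5×-covered sites, popANI = 100 arises by chance even between distinct
lineages (the analogue of the fraction-of-genome-compared filter used
with read-pileup tools in practice).

**Integration.** Each stream yields True, False or *absent* per
(dyad, species). Absent means the method could not be applied — no isolate
on one side, species undetectable in a metagenome, no profiled read pair —
and is deliberately distinct from False: the methods disagree largely
because of differential detectability, so one method's blindness must not
veto another's positive call. The integrated call is the OR over available
flags; when every flag is absent no call is emitted.

## The synthetic cohort

The generator emulates the statistical structure of a real dyad cohort:

* **Genomes.** Random sequences with exact base composition, default
  59.41% GC (the genus median) and 100 kb length. All decision thresholds
  are ratios or counts, so 100 kb exercises the same logic as 2.3 Mb at a
  fraction of the cost; SNP *counts* (not densities) are preserved so the
  <200-SNP rule reads identically. The consequences of that choice are
  handled explicitly below.
* **Lineages.** Per (dyad, species), the mother's lineage is founded a
  uniform draw of 1500–5000 substitutions from the species ancestor, so
  two lineages sit 3000–10000 SNPs apart. A transmitted infant strain is
  derived from the mother's strain at uniform 3–61 SNPs; a non-transmitted
  infant founds an independent lineage. Additional per-individual strains
  (micro-diversity) are Poisson(mean 10) siblings of the primary strain,
  giving within-host distances in the observed 1–121 band; the true
  distribution is unknown, so the mean is configurable.
* **Covariates.** Delivery mode, membrane rupture, labour onset and
  intrapartum antibiotics are drawn from a consistent joint model (onset
  first; mode, rupture and antibiotics conditioned on it; ~60% vaginal
  births). Transmission is an independent Bernoulli per (dyad, species)
  whose probability comes from a per-covariate effect table (averaged when
  several covariates carry tables) or a flat transmitted fraction. The
  real per-covariate probabilities are unknown — only their significance
  was reported — so effect tables are illustrative inputs, not claims.
* **Reads.** Single-end 150 bp reads (pairing adds nothing for popANI at
  this scale), multinomial across genomes with weight abundance × length,
  uniform starts, i.i.d. substitution errors (default 0.2%), flat Phred-40
  qualities. Each stool sample mixes the individual's strains at their
  simulated relative abundances with an environmental background genome
  occupying the remainder, so a species' read yield scales with its
  abundance — the property that creates realistic detection limits.
* **Sample QC.** Samples under a read-count floor are dropped, then
  samples whose dyad partner was dropped (no singletons). The production
  floor is 100,000 post-filtering reads; the pipeline's desk-scale floor
  is 1000.

What the generator does **not** emulate: indels and rearrangements,
plasmids and mobile elements, recombination imports (masking is therefore
a guarded path in the pipeline), contamination, quality-score structure,
and strain replacement over time. Passing tests demonstrate the decision
logic and its calibration on substitution-only variation; they do not
demonstrate robustness to assembly error or structural variation in real
genomes.

## Desk-scale corrections (count-preserving genomes vs ratio thresholds)

Keeping SNP counts fixed while shrinking genomes 23× inflates all
*densities* 23×. Three thresholds are density-based and are adjusted in
the pipeline defaults only (the module-level functions keep the
full-scale defaults):

* **Species clustering** uses 85% ANI instead of 98%: same-species
  lineages sit at 90–97% ANI at desk scale, while unrelated species share
  no mappable fragments at all (undefined ANI), so any threshold below
  ~90% separates species cleanly without splitting lineages apart.
* **Recombination masking** raises its per-window SNP cutoff to
  max(10, 5× the alignment's mean columns per window): a many-lineage
  union alignment at desk scale exceeds any absolute density constant, so
  only windows denser than ordinary vertical divergence are masked. At
  full-scale densities the absolute 10-per-kb rule dominates.
* **Read mapping** accepts reads at ≥ 85% identity instead of 95%, since
  lineages legitimately diverge up to ~10% from the cluster reference at
  this scale.

One density effect is left uncorrected on purpose: 99.999% popANI on
100 kb tolerates less than one divergent site, so the popANI stream only
confirms near-identical populations (transmitted pairs with their few
SNPs falling outside the compared sites). This mirrors the real behaviour
of the method — read-based popANI detected only pairs with essentially
zero population divergence — and is why the integrated OR, not any single
stream, is the headline call.

## Numerical and algorithmic choices

* **Fragment ANI** tiles the query into 1 kb non-overlapping fragments
  (scaled from 3 kb for full genomes), anchors each by exact 16-mer seeds
  sampled every 64 bp, evaluates every distinct implied diagonal ungapped,
  and keeps fragments whose best identity reaches 80%. Ties go to the
  leftmost reference coordinate. Both directions are computed; species
  clustering uses the maximum. Zero retained fragments yields an
  *undefined* ANI (None/NaN), never 0. On substitution-only pairs the
  estimate tracks the exact Hamming oracle to < 0.05 percentage points up
  to 1% divergence (verified in the acceptance suite).
* **Variant calling** is positionwise comparison on shared coordinates,
  guarded by a 21-mer anchor check that rejects unrelated sequences;
  exact for the generator's equal-length substitution-only output, and the
  round trip against injected SNP counts is exact by test.
* **Trees** are neighbor joining on SNP distances (scikit-bio), with taxa
  sorted lexicographically first so tie-breaking is order-independent and
  negative NJ branches clamped to zero. Maximum-likelihood inference with
  ascertainment correction and bootstrap support are out of scope; the
  monophyly and nPD decisions depend on topology and relative lengths,
  which NJ preserves in this regime (verified by recovery of random
  additive matrices). Monophyly is evaluated on the midpoint-rooted tree;
  two-leaf trees are midpoint-rooted analytically.
* **nPD availability** models the marker-profiling detection limit: the
  nPD stream is absent for a dyad when the species' relative abundance in
  either stool sample is below 0.5% (configurable). Without this gate a
  tree built from isolate genomes would make the marker-based stream
  abundance-independent, which it is not in practice.
* **Reference choice** per species cluster: the lexicographically first
  maternal genome, recorded in the outputs. Dereplication for the popANI
  reference set reuses the ANI clusters.
* **Statistics.** Fisher's exact test (two-sided, via scipy, validated
  against exact rational hypergeometric enumeration) for 2×2 tables;
  Pearson chi-square without continuity correction for covariates with
  more than two levels; no multiple-testing correction by default,
  matching the emulated analysis (Benjamini-Hochberg available as an
  option). The unit of analysis is the dyad. Chi-square refuses tables
  with a zero expected cell and directs the caller to Fisher.
* **Determinism.** One root seed is split hierarchically
  (per dyad/genome/read set) via `numpy` `SeedSequence` spawn keys, so any
  sub-component is reproducible in isolation and the full
  simulate → report path is byte-identical across runs.
* **Coordinates** are 0-based half-open in memory; exported variant and
  pileup tables are 1-based (VCF convention). Threshold boundary
  semantics follow the quoted rules: ANI thresholds inclusive (≥), the
  SNP cutoff strict (<200), nPD strict (<0.001), popANI inclusive
  (≥99.999) with strict breadth (>50%).

## Problem sizes used in validation

The test and acceptance suites run: 50 ANI oracle pairs at 100 kb; a
20-dyad cohort for exact SNP round trips; the default 40-dyad, 2-species
cohort (20,000 reads per sample) for nPD calibration and integrated
recovery; 20 fixed-seed popANI replicates at ~10× depth; 300 random
2×2 tables (N ≤ 40) against the Fisher enumeration oracle plus 500 null
cohorts for type-I calibration; and a 4-dyad end-to-end run executed twice
for bytewise determinism. These sizes are the package's validation
envelope; all are configurable upward.

## Known limitations

* Ungapped seed-anchored placement (both fragments and reads) is blind to
  indels and rearrangements; real draft assemblies need an external
  aligner upstream.
* The recombination mask is a density heuristic, not a model-based
  detector; it exists to keep imported tracts out of SNP distances, not to
  delineate recombination precisely.
* Direction of transfer is labelled mother → infant by construction;
  the package does not infer directionality from data.
* Bootstrap support, ML trees, and inStrain's wider microdiversity
  statistics (conANI, nucleotide diversity, linkage) are not implemented.
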