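# Methods

`crcprofiler` re-implements, as a tested and reusable library, a
profiling workflow for colorectal tumor cohorts: evidence-aggregated
somatic-variant prioritization, allele-specific copy number with tumor cell
content (TCC) and ploidy estimation, MSI/TMB cohort characterization,
footprint-based pathway/TF activity inference, patient stratification and
interventional-basket assignment. Because the cohorts such workflows run on
are controlled-access, the package ships a first-class synthetic-cohort
generator with recorded ground truth; every stage is validated against that
truth rather than against any particular dataset.

## Variant scoring

Each annotated variant carries four evidence sub-scores in [0, 1]
(pathogenicity predictions, cancer knowledge bases, clinical support, and
cohort expression of the affected gene — 1 iff the gene has ≥ 10 read
counts in ≥ 5 samples). The aggregate score is a weighted arithmetic mean;
weights default to equal and are config-exposed because the relative
importance of evidence sources is a policy choice, not a measurement. With
binary evidence the score equals the supported-category fraction, so the
≥ 0.5 prioritization cutoff is exactly the "at least two of four
categories" rule; this equivalence is asserted over all 16 binary profiles
and 1000 random binary tables. Upstream filtering keeps variants with
caller confidence ≥ 8 of 10. One sub-score per category is taken as input;
aggregating multiple resources *within* a category is out of scope, as the
annotation retrieval itself is.

Transcript selection: the gene's MANE Select transcript when it appears
among the annotated transcripts; otherwise the highest-impact consequence
according to a packaged, editable ordering (stop_gained > frameshift >
splice > missense > in-frame > synonymous), ties broken by transcript
length and finally lexicographically so the choice is deterministic.

## Copy number, purity and ploidy

The coverage model links a segment's tumor/normal coverage ratio `r` to its
total tumor copy number `ct` at purity `tcc` and normalization ploidy
`ψ`:

    r = (tcc·ct + 2(1 − tcc)) / (tcc·ψ + 2(1 − tcc))

and, for allelically imbalanced segments, the observed decrease of
heterozygosity `dh_obs = 2·BAF − 1` (folded B-allele frequency, using the
higher-count allele as B-allele) to the allele split:

    dh_obs = tcc·(cA − cB) / (tcc·ct + 2(1 − tcc)).

Heterozygous SNPs are those with normal-sample allele fraction in
[0.3, 0.7] (boundaries inclusive). Segments with ≥ 20 het SNPs are
classified from the Gaussian-KDE density of the *unfolded* tumor allele
fractions (Silverman bandwidth; peaks are local maxima with prominence
≥ 10% of the density maximum): global maximum in [0.45, 0.55] → balanced;
one peak elsewhere → ambiguous (excluded from fitting); two peaks →
imbalanced. The KDE is evaluated on a grid extended ~4 bandwidths beyond
[0, 1]; otherwise modes near 0 or 1 (strong LOH at high purity) lose
prominence against the truncated tail and go undetected.

The (tcc, ploidy) grid spans [0.05, 1] × [1, 6.5] at steps 0.01 / 0.05
(config-exposed). Each cell's cost is the segment-length-weighted mean
distance of the implied real-valued copy numbers to their nearest allowed
integer states — even total states only for balanced segments; for
imbalanced segments the allele-specific distances |cA − round(cA)| +
|cB − round(cB)| are added (an explicit |dh| term is available behind the
`dh_term` flag but off by default). Cells are infeasible when any segment
implies a negative total copy number, or an imbalanced segment implies
tumor DH materially above 1 — operationalized as the *nearest minor-allele
state* being negative (cB < −0.5). A strict cB < 0 rule would reject the
true solution for any pure-LOH segment whose noisy BAF overshoots the
boundary (and even noiselessly, through floating-point round-off); small
overshoots are charged as distance instead.

Solutions are feasible local minima of the cost surface (8-neighborhood);
ranking is by ascending distance with numerical ties broken toward lower
ploidy, then higher TCC. Harmonic degeneracies are real: a diploid tumor
at purity `t` fits exactly as a hexaploid tumor at `t/(3 − 2t)` whenever
the implied states stay integral, which is why candidate solutions are
reported as a ranked list rather than a single answer (the workflow this
replaces resolved the choice by eye; the ranked list plus the tie-break
toward parsimonious ploidy is the scriptable equivalent). Validation:
noiseless forward simulations at {0.3, 0.6, 0.9} × {2, 3, 4} are recovered
exactly at grid resolution; with binomial BAF noise (depth 100, 30
SNPs/segment, 20 segments) the truth is in the top-2 ranked solutions in
≥ 95% of 50 replicates.

## Cohort characterization

MANTIS-like instability scores are thresholded at > 0.6 (MSI) and < 0.4
(MSS), the closed interval in between being Undetermined; MSI-L labels are
grouped with MSS. TMB is protein-altering mutations (missense, stop
gained/lost, splice site, frameshift, in-frame indel) per megabase; the
capture size defaults to 35 Mb and is a required config value since it is
a property of the exome kit, not of the data tables. The six-class
substitution spectrum collapses purine-reference SNVs onto the pyrimidine
strand. Differential mutation frequency between MSI and MSS uses the
two-sided Fisher exact test (conventional definition: summing
probabilities of tables at most as probable as the observed one) per gene,
restricted to genes mutated in ≥ 4 samples, with Benjamini–Hochberg
adjustment and an adjusted-p ≤ 0.1 significance flag. Over-representation
uses the hypergeometric upper tail and reports the rich factor (hit count
over annotated set size). Both exact tests are checked against
fixed-margin / subset enumeration oracles.

## Activity inference

The footprint statistic is the |w|-normalized weighted mean
`score(s) = Σ w·x / Σ |w|` over a source's measured targets (minimum 5 by
default). Its normalized enrichment score (NES) is a z-score against a
null of `n_perm = 1000` gene-label permutations; the permutation p-value
is two-sided empirical with +1 smoothing. On null data the NES is
calibrated (|mean| < 0.1, |sd − 1| < 0.1 across 500 random regulons) and
|NES| ≥ 2 is the significance convention throughout. Pathway scoring
restricts each pathway's dense weight vector to its top-100
most-responsive genes (largest |weight|) before applying the same
statistic. Per-sample activities feed each sample's per-gene z-score
(computed across samples; constant genes dropped) through the same
machinery with a shared permutation schedule so columns are comparable.

The group contrast statistic is a per-gene Welch t (MSI − MSS) on filtered
log2-CPM expression. TMM/voom moderated statistics are deliberately not
reproduced — the contrast enters the weighted mean only as a per-gene
ranking-scale statistic, and the Welch t is the assumption-light choice.
Expression filtering keeps genes with ≥ 10 counts in ≥ 5 samples (the
package's single reading of the intensity-filter rule, stated here because
a "less than … in less than …" phrasing is ambiguous) followed by
counts-per-million and log2(x+1).

ssGSEA: expression is z-score-corrected per gene across samples, genes are
ranked per sample by the corrected value, and the enrichment score is the
*sum* (projection form, not the running maximum) of the difference between
the |r|^α-weighted in-set ECDF and the uniform out-of-set ECDF, α = 0.75,
minimum overlap 10. Sets covering the entire matrix have no out-of-set
ECDF and are skipped. p-values come from random same-size member sets. The
implementation is verified to 1e-9 against an independent ranked-walk
oracle on random instances.

Kinase/enzyme networks are pre-filtered before inference: edges supported
only by a text-mining resource (ProtMapper) are dropped unless confirmed
elsewhere, only phosphorylation/dephosphorylation events are kept, and
(source, target, modification) duplicates are removed.

## Stratification and actionability

Patients are clustered on their per-sample activity matrix by the
hierarchical-clustering-on-principal-components recipe: standardize
features, retain the smallest number of principal components whose
cumulative explained variance reaches 95%, Ward-linkage clustering on the
component scores, cluster count chosen in [2, 10] by the largest relative
loss of within-cluster inertia between successive cuts, then k-means
consolidation seeded from the hierarchical centroids. The inertia-gain
rule assumes the separation lives in the retained components; when most
features are pure noise the rule (like the tools it mirrors)
conservatively under-splits — the planted-cluster validation therefore
uses blobs separated across the feature space.

Actionability: prioritized variants are matched to a knowledgebase,
keeping only Oncogenic / Likely Oncogenic records (exact protein-change
records take precedence over gene-level "any" records) and attaching
therapeutic evidence levels (1–4 sensitivity, R1/R2 resistance). Basket
assignment is the union of the basket labels of the patient's actionable
mutated genes — assignment is monotone in the mutated-gene set — plus the
immune-evasion basket iff the tumor is MSI or TMB ≥ 10 mutations/Mb (the
high-TMB boundary is config-exposed; 10/Mb is the widely used
immunotherapy-eligibility convention). By default only *actionable*
variants drive baskets; a flag-free alternative is to pass the full
prioritized table to the same function.

## Synthetic cohorts

The generator emulates the study conditions the pipeline is meant for:

* **Variants** — Poisson mutation counts with means 1257 (MSI) and 108
  (MSS) per tumor, the published cohort medians; MSI tumors draw an
  elevated frameshift fraction (0.25 vs 0.07). Evidence categories are
  supported independently with probability 0.3; a supported category is
  fully supported (1.0) with probability 0.4 and Beta(8, 2)-distributed
  otherwise. Caller confidence is skewed high (85% ≥ 8).
* **Segments** — forward simulation of the coverage/BAF model above from a
  known (tcc, ploidy, per-segment cA/cB) truth; BAFs are
  binomial(depth)-sampled at the expected unfolded allele fraction, the
  alternative allele landing on either haplotype with probability 1/2.
  Default 20-segment profiles mix balanced states with strong-LOH states
  and include odd total copy numbers so harmonic degeneracies cannot fit
  exactly. The coverage noise model is a stand-in (Gaussian on log2 ratio,
  off by default) since no empirical noise model is specified for the
  workflow this emulates.
* **Expression** — negative-binomial counts (lognormal gene means,
  dispersion 0.2); a planted source with effect δ scales its targets'
  means by 2^(δ·w) in the designated group (the MSI patients in cohort
  simulations). Regulon weights are ±1 (80% positive), the convention of
  curated regulon resources.
* **Fixtures** — small self-consistent knowledgebase, basket map (all
  seven baskets represented), driver list, MANE transcript map and GMT
  gene sets (≥ 10 members each).

What the generator does *not* emulate: trinucleotide mutational contexts
and signatures, read-level data, GC/mappability coverage waves, subclonal
copy-number states, and realistic gene–gene expression correlation. A
green suite therefore demonstrates that the algorithms are correct under
their stated models, not that the models capture every property of real
tumors.

## Numerical choices

Interval boundaries are inclusive throughout ([0.3, 0.7], [0.45, 0.55],
score ≥ 0.5, confidence ≥ 8, |NES| ≥ 2; MANTIS boundaries 0.4/0.6 fall to
Undetermined). All randomness flows through `numpy.random.default_rng`
seeds carried in the configuration; pipeline reruns with the same
configuration are byte-identical. Problem sizes in the validation suite —
50 purity replicates, 500 segments per class, 500 null regulons, 100
planted simulations, 30-patient end-to-end cohorts — were chosen as the
smallest sizes at which the binomial uncertainty of the measured rates is
comfortably below the margins being asserted.
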