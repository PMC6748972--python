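# Methods

`invpopkit` re-implements, as a tested library plus a set of analysis
drivers, the computational stack used to characterise common polymorphic
chromosomal inversions in human populations: linkage and tagging structure,
unique-versus-recurrent origin inference, divergence-based dating,
ascertainment-aware frequency analysis, selection scans and functional
association. Every stage runs at desk scale against the package's own
synthetic-data generator, which also supplies ground truth for recovery and
calibration tests.

## The inversion model and the synthetic-data generator

An inversion has two orientations, O1 (the orientation of the reference
assembly — never assumed ancestral) and O2. In heterokaryotypes, single
crossovers inside the inverted span produce unbalanced gametes, so
effective crossing over **between** orientation classes is suppressed
inside the span, while exchange **among** same-orientation chromosomes is
unaffected. The generator (`invpopkit.synthdata`) realises this with the
structured coalescent in msprime:

- The O1 and O2 classes are sub-populations with zero migration.
- Each origin event is a **single founder chromosome**: the derived deme is
  forced to full coalescence at the event time (instantaneous bottleneck)
  and the founder lineage then merges into the O1 background. Without the
  founder constraint, incomplete lineage sorting puts shared variants
  inside the span and the model stops matching inversion biology.
- A unique origin of age `T` generations is one such event; a recurrent
  inversion is `k` independent events. Recurrent realisations are redrawn
  (bounded retries) until small parsimony on the true local genealogy
  equals `k` and each pair of derived demes has at least two maximal
  O1-only clades under their joint ancestor — otherwise "k independent
  events on distinct backgrounds" is not actually realised (two derived
  sister clades are explained more cheaply by one older flip plus a
  re-inversion).
- The O1 deme and the ancestral population share the effective size `Ne`,
  and the derived deme defaults to `f·Ne/k` (configurable via
  `derived_deme_size`), so the expected net divergence
  `π_between − max(π_within)` equals `2·μ·T` — the identity the dating
  module relies on.
- Flank exchange: outside the span, crossovers between orientation classes
  are emulated by explicit swap events whose expected number follows the
  ancestral-recombination-graph scaling `4·Ne·r·L·H(n−1)` thinned by
  `2f(1−f)`; sites farther from a breakpoint are shuffled by more events,
  so the shared-variant fraction rises with flank distance, as seen around
  real unique inversions.
- Gene conversion is an explicit short-tract copy (default 200 bp) between
  random opposite-orientation haplotypes; the default rate is 0 because
  only qualitative evidence for it exists in this setting.
- Mutations use a binary model restricted to single-mutation sites
  (infinite-sites behaviour: every variant marks one clade). With
  `discrete_positions=False` positions are continuous and arbitrarily high
  mutation rates can be simulated without homoplasy; the default keeps
  integer positions for VCF round-tripping.

The target inversion frequency is realised **exactly** by the sample
composition of the structured model (number of haplotypes drawn from each
deme), rather than by rejection sampling over replicates; retries are used
only where a qualitative constraint must hold (distinct recurrent
backgrounds, parsimony-consistent chromosome-Y event placements).

What the generator does *not* emulate: realistic human demography (at most
a constant-size background), mutation-rate heterogeneity, genotyping error,
phasing error beyond what the recurrence estimator is asked to prune, and
accessibility-mask structure (the mask is a user-supplied flag). Passing
tests therefore demonstrate correctness of the algorithms under the stated
model, not robustness to every artefact of real cohort data.

## Linkage and variant classification

`ld_r2` computes haplotype r² as `D²/(p_A p_a p_B p_b)` by direct gamete
counting when both vectors are phased, and the composite squared
dosage-correlation otherwise (phase-free; reduces to the haplotype value
under Hardy–Weinberg proportions). Variants are classified against the two
orientations using only *unambiguous* evidence — inversion homozygotes and
hemizygotes, plus variant-homozygotes among heterokaryotypes (the same
allele must sit on both orientations) — unless labeled haplotypes are
supplied: **fixed** (the orientations carry different, internally
monomorphic alleles; r² = 1 on the evidence chromosomes), **shared** (both
alleles unambiguously observed on both orientations), **private** to one
orientation, or **unassigned**. A property test checks the evidence sets
against brute-force enumeration of every phase-consistent
allele-to-orientation assignment.

The non-recombining flank on each side is the longest interval outside the
breakpoints (up to 20 kb) without a shared variant compatible with
crossing over. An isolated shared SNP bracketed by fixed/private variants
within 1 kb on both sides is treated as gene-conversion evidence and
skipped (bracket distance configurable). When the scan stops early, the
flank is truncated at the outermost fixed variant inside the stopping
point; a fraction-based rule (keep ≥ 90 % of fixed variants) and a plain
stop-at-variant rule are available by flag.

## Recurrence estimation

Haplotypes are labeled by perfect tag variants (r² = 1) when they exist,
otherwise only the haplotypes of inversion homozygotes/hemizygotes are
labeled. Hierarchical clustering (Hamming distance over accessible sites;
complete or average linkage; rows canonicalised before clustering so the
dendrogram is invariant to input order) stands in for the genealogy — the
same visual-cluster logic used when such calls are made by eye, made
deterministic. Likely phasing errors are pruned first: a haplotype from a
heterokaryotype lying within `max_error_diff` (default 2) differences of an
opposite-orientation haplotype *and closer to the opposite class than to
its own* is relabeled; identical haplotypes carried by both orientations
are genuine recurrence evidence and are never pruned. The minimum number
of orientation state changes on the dendrogram is then computed by exact
small parsimony (Sankoff dynamic programming, valid for multifurcations
and for a fixed root state), and `events = changes − 1` because the
original inversion is not recurrence. `min_support` flags event clusters
below a chosen size. On the recombination-free chromosome-Y genealogy the
same parsimony count divided by the total branch length in generations
gives an inversion rate, with a Poisson exact confidence interval.

Average linkage recovers the true event count slightly more reliably than
complete linkage in simulations (it better approximates the ultrametric
coalescent tree); the recovery test uses it. The estimator is a minimum:
when two true origins land on backgrounds that the clustering cannot keep
apart, it undercounts — which is the conservative direction.

## Dating

`age = (π_between − max(π_within_O1, π_within_O2)) / (2·rate)`, with the
larger within-orientation diversity as the ancestral-diversity correction
and the factor 2 because divergence accrues on both lineages since the
origin. π values are per-site means of pairwise Hamming differences over
accessible sites in the inverted span plus any non-recombining flank.
Rates are accepted per year (default) or per generation, converted through
a configurable generation time (default 29 years). Non-positive net
divergence is reported as a non-positive, undetermined age — never
clipped. Confidence intervals come from resampling *individuals* with
replacement (default 1000 times) and taking percentile 2.5/97.5 bounds;
resampled diversities use the multiplicity-weighted U-statistic form that
excludes pairs of copies of the same haplotype (naive recomputation lets
duplicate individuals contribute zero-distance pairs, deflating π_within
and mis-centring the interval).

Known limitation, demonstrated quantitatively by the test suite: the
individual-resampling bootstrap can only represent the *sampling* share of
the estimator's error. The Poisson draw of mutations on the single founder
branch and the genealogy draw are shared by all individuals and are
invisible to any resampling of individuals, so the percentile interval is
anticonservative for the true age; across a wide range of simulated
regimes its realised coverage tops out near 75 % rather than 95 %. The
corresponding acceptance check is left failing by design, with the point
estimator's low bias (median relative error within 15 % across ages
500–8000 generations) verified separately.

## Frequency analysis under ascertainment

Discovery of inversions happened in small panels (nine diploids for the
paired-end-mapping set; one assembly comparison for the rest), which
enriches common alleles. `simulate_detection` reproduces the two-step
process on a SNP pool: (1) keep variants polymorphic within the discovery
individuals; (2) draw matched SNPs with probability proportional to a
detection-probability function. The default detection model is the
carrier-presence probability `1 − (1 − p̂)^m` computed from the allele
frequency observed *in the discovery panel* (the data the detection step
operates on), times a length factor of 1; the function is pluggable. On a
neutral 1/i spectrum this yields a mean ascertained MAF of ≈ 0.20
(closed-form integration gives 0.203), the package's headline
reproduction. Empirical frequency tests use the two-tailed convention
p = 2 × (fraction of null samples at least as extreme), capped at 1.

The Hardy–Weinberg QC is the exact conditional test (sum of
heterozygote-count probabilities no larger than the observed one),
verified against integer-rational enumeration. Frequency determinants are
fitted by M-estimation (Tukey bisquare) with forward selection at a 0.05
robust-test entry threshold; variance explained is a robust pseudo-R²
(one minus the squared ratio of residual to total M-scale), since no
canonical definition exists for robust fits.

## Selection scans

- **F_ST**: Weir–Cockerham variance components (a, b, c) per locus, with a
  two-component haploid analogue for chrY and male chrX; multi-locus value
  Σa/Σ(a+b+c). Empirical percentile against SNPs matched on frequency
  (bin half-width 0.02, widened with a record when matches are scarce);
  top 1 % = strong, top 5 % = weak.
- **LSFS**: the frequency spectrum of variants linked to the inverted
  allele, each variant annotated nested / disjoint / discordant by its
  carrier-set topology relative to the inversion carriers (discordant
  variants are tallied but excluded from the statistic — under the model
  they indicate exchange between backgrounds). The statistic is linear,
  `T = w·ξ` normalized by the window variant count, with weight vectors
  `w ∝ (E_alt[ξ] − E_null[ξ])/SD_null[ξ]` estimated once from seeded
  simulations of a sweep-like alternative (young origin at frequency 0.8
  on a star-like background) and a balancing-like alternative (40,000
  generation-old origin held at frequency 0.5), stored versioned in
  `src/invpopkit/data/lsfs_weights.json` and regenerable by
  `analysis/06_selection_scans.py --regenerate-weights`. Windows are
  tested against an empirical null bank conditioned on the focal-allele
  frequency (tolerance 0.05), p = (r+1)/(n+1); per-population p-values of
  a window combine by Edgington's method (exact Irwin–Hall tail up to 30
  values, normal limit beyond); across windows both a conservative
  (Bonferroni-adjusted minimum) and an approximate (Edgington across
  windows) combination are reported, as an explicit interpretation choice.
- **NCD**: `NCD(tf) = sqrt(Σ (MAF_i − tf)² / n_IS)` at target frequencies
  0.3/0.4/0.5 in 2-kb windows with 1-kb step; NCD2 adds interspecies fixed
  differences as MAF-0 sites. Windows need ≥ 8 informative sites and
  ≥ 16.7 % alignment coverage; failing windows are excluded, not scored.
  An inversion is summarised by its minimum-NCD window and tested
  lower-tail against a genome bank of same-size regions, p = (r+1)/(n+1);
  signals are classified by detection in ≥ 3 populations.

## Expression and trait association

Expression is adjusted for supplied covariates plus expression principal
components (defaults 10 for genes, 20 for transcripts; rank-deficient
covariates dropped), residuals are mapped to N(0,1) through Blom-offset
ranks, and the inversion's O2 dosage enters an additive linear regression
for every feature expressed in ≥ 20 % of samples with TSS within 1 Mb.
q-values are Benjamini–Hochberg across all tested pairs; a
genotype-permutation negative-control mode mirrors the original study's
check. The joint analysis ranks the inversion among local variants by
nominal p (ties by |effect| then identifier). GWAS signals are
deduplicated into loci by single-linkage chaining (±100 kb or r² ≥ 0.8,
same phenotype — transitive, for determinism), and enrichment in the
inversion ± 20 kb is tested against matched random regions (mean variant
frequency within 0.01; chi-square p > 0.05 on the MAF </≥ 0.2 split;
gaps and chrY excluded), one-tailed p = (r+1)/(n+1).

## Numerical and testing choices

All stochastic procedures take explicit seeds and are bit-reproducible.
Empirical p-values from banks use (r+1)/(n+1) to avoid zero; the
"twice the fraction" two-tailed rule is kept where the original analysis
states it (frequency tests). Problem sizes in the test-suite simulation
studies (cohorts of 6–30 diploids, regions of 2 kb–4 Mb, 100–200
replicates) were chosen so that each check has adequate signal-to-noise at
desk scale; the site-frequency-spectrum goodness-of-fit test uses a low
per-replicate θ because shared genealogies overdisperse class counts and
would invalidate the chi-square reference otherwise. Degenerate inputs
(monomorphic vectors, empty windows, one-orientation resamples,
insufficient null banks) return missing values or raise typed errors
rather than silently producing numbers.
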