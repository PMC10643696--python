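# Methods

This note documents the statistical models, algorithmic conventions and
design choices behind each stage, and what the simulator does and does not
emulate.

## Data model

Genotypes are alternate-allele counts in {0, 1, 2} with a distinct missing
sentinel (−1), stored as a samples × variants `int8` matrix. Coordinates
are 1-based and inclusive, as in VCF; the one exception is the truth BED
export, which follows the 0-based half-open BED convention. Variants are
sorted by natural chromosome order (chr2 < chr10) then position, which
makes every report deterministic without needing a reference index.
Half-calls (`0/.`) are treated as missing — conservative, and consistent
with the downstream missingness filters. Sex labels are normalized from
{m, male, f, female} case-insensitively; anything else becomes `unknown`
and is excluded from breeding pools.

## Quality control

Filters run in a fixed order: samples with missing fraction ≥ 0.15 are
dropped first; variant statistics are then recomputed on the remaining
samples; variants fail on missingness > 0.10 (strict), MAF < 0.05
(strict), or Hardy–Weinberg exact-test p < 0.01. The sample filter runs
first because cohort-level variant statistics should not be distorted by
low-quality individuals. The HWE criterion is read as "exclude significant
departures from equilibrium", i.e. drop p < α — the standard `--hwe`
semantics. The exact test conditions on the allele counts and sums the
probabilities of all heterozygote counts no more likely than the observed
one (plain exact p, not mid-p). It is evaluated with a log-space
recurrence over heterozygote counts, numerically stable for totals well
past 10⁴; the test suite verifies exact agreement with an independent
integer-arithmetic enumeration oracle for every table with total ≤ 200.
Applying the filter twice removes nothing (idempotence is tested).

## LD pruning

r² is the squared Pearson correlation of genotype counts (composite LD) —
appropriate for unphased data — with pairwise deletion of missing calls;
undefined r² (zero variance, < 2 complete pairs) counts as 0. Pruning uses
the common window-50 / step-5 / r² > 0.5 idiom, exposed in config, since
tools differ and the choice materially affects the retained count. Within
each window the pair scan is deterministic: while any kept pair exceeds
the threshold, the later variant (higher position) of the first offending
pair in index order is removed. Pairwise r² does not change when other
variants are removed, so each window's r² matrix is computed once.

## Diversity and inbreeding

Heterozygosity is the fraction of heterozygous calls among non-missing
ones. The inbreeding coefficient is the moments estimator
F̂ = (O_hom − E_hom)/(L − E_hom), where the per-variant expected
homozygosity under HWE uses the small-sample factor 2n/(2n−1) to correct
the downward bias of plug-in expected heterozygosity. Allele frequencies
come from the full post-QC cohort (single-cohort semantics), not per
subpopulation. Negative F̂ (heterozygosity excess) is reported as-is;
samples with a degenerate denominator (all variants monomorphic) get NaN.
Group summaries report mean ± sample SD (n−1), min and max; because the
appropriate two-group test is context-dependent, both Welch's t and
Mann–Whitney U are computed for every pair (Welch is the headline), and
pairs involving groups of fewer than two samples are skipped with a
warning.

## Relatedness

IBS states per locus: 2 if genotypes are equal, 0 for opposite
homozygotes, 1 otherwise, over loci complete for the pair. The IBD moments
estimator accumulates the expected IBS-state counts conditional on each
IBD state (P(IBS0|Z0) = 2p²q², P(IBS1|Z0) = 4p³q + 4pq³,
P(IBS2|Z0) = p⁴ + q⁴ + 4p²q², P(IBS1|Z1) = 2pq, P(IBS2|Z1) = p² + q²,
P(IBS2|Z2) = 1) and solves for ẑ₀, ẑ₁, ẑ₂ in sequence, then clamps to
[0, 1] and renormalizes onto the simplex; π̂ = ẑ₂ + ½ẑ₁. Plug-in cohort
allele frequencies are used deliberately, without finite-sample correction
factors: the uncorrected estimator is fully specified here, and accuracy
is validated by pedigree recovery (parent–offspring and full sibs within
[0.45, 0.55], half sibs within [0.20, 0.30], unrelated ≤ 0.05 at 10k
quasi-independent SNPs). Relatedness is computed on the filtered,
LD-pruned SNP set only. All-pairs computation is done with indicator-
matrix products, so missing patterns are handled exactly per pair.

The relationship classifier follows the published percentage criteria with
their boundary conventions verbatim: duplicate/twin is strict (> 0.95),
the remaining tiers inclusive (≥ 0.40, ≥ 0.20, ≥ 0.10). Classification
uses raw π̂, not percentage-rounded values.

MDS is classical (Torgerson): double-center −½D² for the IBS distance
D_ij = 1 − (IBS2 + ½·IBS1)/N_ij, eigendecompose, scale the top
eigenvectors by √eigenvalue; negative eigenvalues are clipped to zero. The
embedding is deterministic up to sign, resolved by forcing the first
nonzero loading of each dimension positive.

## Runs of homozygosity

Windows of 15 consecutive SNPs slide one SNP at a time; a window is
homozygous when it has ≤ 1 heterozygous and ≤ 1 missing call. Only full
windows are formed — no truncated windows at chromosome edges; a SNP's
score is the homozygous fraction of whatever full windows cover it, and
the SNP is in-run when that fraction exceeds 0.05. Candidate runs are
maximal stretches of in-run SNPs, split at inter-SNP gaps > 1 Mb, and kept
when they have ≥ 20 SNPs, span ≥ 250 kb and have ≥ 1 SNP per Mb
(min density 1/1000 per kb — exposed in config because the convention is
ambiguous across implementations). Opposite/missing calls inside a run are
unbounded. Run length is end SNP position minus start SNP position,
consistent with the Mb arithmetic of the dating formula. With stochastic
flanking genotypes a detected run can extend up to roughly one window span
beyond a true autozygous tract boundary, since a single homozygous window
is enough to mark a SNP in-run at threshold 0.05; recovery tests therefore
allow a window-span boundary error.

F_ROH divides total ROH length by the SNP-covered map extent
(Σ per chromosome max − min position) rather than an assembly length,
because it is computable from the input alone; callers may pass a genome
length override. Length classes are half-open: [0,6), [6,12), [12,24),
[24,48), [48,∞) Mb. Generation dating uses g = 100/(2rL) with
r = 1.04 cM/Mb (a deer linkage-map estimate) and L in Mb: a 24-Mb tract
implies a common ancestor just over two generations back; a 50-Mb tract
implies under one generation.

## Ancestry

The admixture model is the standard binomial mixture: g_il ~ Bin(2, p_il),
p_il = Σ_k q_ik f_kl. It is fit by plain EM — allele-copy responsibilities
for alternate and reference copies, closed-form updates for Q and F —
rather than the block-relaxation/quasi-Newton acceleration of the original
tool: the stationary points are identical and plain EM is far easier to
verify (the non-decreasing log-likelihood is asserted per iteration in
tests). Parameters are clipped to [1e-6, 1 − 1e-6]; Q rows renormalized.
Five seeded restarts by default, best final log-likelihood kept, all seeds
logged. The log-likelihood omits the constant binomial coefficient term.
Defaults tol = 1e-4 (absolute Δ log-likelihood) and max_iter = 1000
suffice for ancestry-fraction accuracy at the problem sizes used here
(recovery to < 0.05 mean error at FST 0.2, 5000 SNPs, 40 samples).

K is chosen by entry-masking cross-validation: random folds of observed
genotype entries are masked (not whole individuals — well-defined without
held-out samples and in the spirit of the original CV), the model is refit,
and masked entries are scored by binomial deviance of the predicted dosage
2p̂; fold errors are averaged. Three folds by default; deterministic given
the seed. Variants left with no training observations in a fold are
skipped with a warning.

Cluster labels are arbitrary, so clusters are aligned to reference
subpopulation labels greedily by maximal mean ancestry fraction (bijective
when K equals the label count; ties resolve in label sort order). Purity
grading operationalizes "100% ancestry" with a numeric tolerance —
purebred requires dominant fraction ≥ 0.999 — because interior-point
clipping makes literal 1.0 unattainable; any minor fraction > 0.40 grades
the individual admixed; everything between is low admixture.

## Breeder selection

"Genetically unrelated" is strictly the classifier's unrelated class
(π̂ < 0.10) on raw values. Candidates and mates are disjoint by sex;
unknown-sex individuals are excluded with a warning; purity gating
(candidates, mates, or both) restricts a side to purebred individuals.
Each candidate's report counts unrelated mates, lists them, and assigns a
tier: unrelated to the whole pool, unrelated to more than 10 (cutoff
configurable), or other. Reports are pure functions of their inputs —
rerunning reproduces identical bytes — and a conservation check (sum of
counts equals the number of unrelated candidate × mate pairs) is tested.
Female-centric reports are produced symmetrically.

## Simulator

Two subpopulation frequency sets are drawn from the Balding–Nichols model:
ancestral frequencies uniform on [0.05, 0.95], subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) at divergence F (default 0.2, a
subspecies-scale value). Pedigrees are simulated by gene dropping: founder
haplotypes are Bernoulli draws from their population's frequencies, and
each meiosis places crossovers as a Poisson process at 1.04 cM/Mb (no
crossover interference — adequate for moments-level truth). Founder-allele
origin is tracked per locus, so the exported truth contains *realized*
quantities: pairwise IBD-state fractions and π̂ from the actual
transmitted alleles, per-sample autozygous segments (both haplotypes from
the same founder allele), realized ancestry fractions, plus
pedigree-expected kinship from the tabular method. Genotyping error
(a call replaced by one of the other two genotypes) and missingness are
applied after truth extraction. Admixed individuals are built as ancestry
mosaics: per-haplotype segments at Poisson breakpoints, each segment's
source population Bernoulli(q_target). All randomness flows through one
seed; identical seeds give identical outputs.

Default noise rates in the demo scenario are 2% missing calls and 0.1%
genotype error — inside the QC filter envelope (≤ 10% per variant, ≤ 15%
per sample) so the scenario exercises the filters without being dominated
by them. Recovery tests use a ten-chromosome, 50-Mb-per-chromosome map:
with only a handful of chromosomes the realized IBD of a single pair has
very large variance (a whole chromosome often segregates without
crossover), while ten autosomes give the mean over 50 replicate pairs a
standard error comfortably inside the stated recovery bands; a
mammalian-style multi-chromosome karyotype is also simply the realistic
choice. Problem sizes used in tests (5–10k SNPs, tens of samples, 50
replicate pairs/pedigrees) were chosen as the smallest scales at which the
Monte-Carlo error of the recovery statistics is small relative to the
acceptance bands.

What the simulator does **not** emulate: background linkage
disequilibrium within populations (variants are drawn independently given
ancestry, so LD arises only from family structure and admixture),
mutation, selection, genotype-calling depth effects, allele-frequency
ascertainment bias of RAD-style SNP discovery, and sex chromosomes.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to every
artifact of real reduced-representation sequencing data.

## Numerical conventions and degenerate inputs

- Monomorphic variants contribute nothing to F̂ (numerator and denominator
  terms cancel); an all-monomorphic cohort makes IBD expectations
  non-positive and is a hard error.
- A pair with zero complete loci is a hard error, as is a sample with no
  non-missing genotypes.
- MAF of an all-missing variant is undefined and fails QC.
- MDS eigenvalues below zero (non-Euclidean distances) are clipped.
- All report files are TSV with headers; ordering of rows and columns is
  fixed by (subpopulation, sample id) or genomic position, never by hash
  order.

## Known limitations

- The moments IBD estimator assumes a homogeneous cohort; in strongly
  structured cohorts (two subspecies pooled) cross-group π̂ is biased
  upward, which is why relatedness interpretation is done within
  subpopulation groups.
- Entry-masking CV can prefer smaller K when the masked fraction is large;
  with two folds on small cohorts K = 1 occasionally wins on genuinely
  structured data. Three folds are the default.
- The ROH detector reports tract boundaries at SNP positions; with sparse
  maps the physical boundary uncertainty is the local SNP spacing plus up
  to one window span.
- F_ROH uses map extent as denominator, so values are comparable within a
  dataset but not across datasets with different map coverage unless a
  genome-length override is supplied.
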