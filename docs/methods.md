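# Methods

This note documents the models, numerical choices, and open design
decisions behind `pcsnp`, in the spirit of the methods documentation of
simulation and statistics packages: what exactly is computed, which knobs
matter, and what the synthetic validation does and does not demonstrate.

## Data model

A data set is an m x n integer matrix S of additive genotype codes — the
count of the alternate allele at each SNP, so 0 and 2 are the two
homozygotes and 1 the heterozygote — plus one breed label per sample.
Missing calls are coded -1. Any selection or classification run requires
at least two distinct breeds. Imputation replaces each -1 with the most
frequent observed code *in its own SNP column*; ties between candidate
modes break toward the smallest code so the operation is deterministic and
auditable. Imputation is idempotent and touches nothing but missing
entries. A column with no observed call at all is an error (its mode is
undefined), not silently filled.

## Splitting scheme

The outer experiment uses an 80:20 train/test split; the frequency
consensus then re-splits the training set into r = 10 sub-train/sub-test
pairs with seeds seed0 … seed0+r-1, so one integer reproduces an entire
experiment. Both levels are stratified by breed: per breed,
round(fraction x breed size) samples go to the test side (never a whole
breed). Whether the original experiments stratified is not documented;
stratification is the default here because unstratified splits of small
breeds can produce empty classes, and it is toggleable in
`genotype_io.stratified_split` only insofar as singleton breeds can be
routed to the training side instead of raising. The inner sub-split
fraction is not pinned by any published value; it defaults to 0.2,
mirroring the outer ratio, and is exposed in `PipelineConfig`.

## Information gain and the elbow cut

Entropy is base-2 (`0 log 0 = 0`), so all gains are in bits and bounded by
the label entropy. Genotype codes are treated as *unordered* categories
{0, 1, 2}; no binning or ordinal treatment. Ranking is stable: ties keep
the original column order. The gain is computed per training sub-split,
not once globally, so each of the r consensus runs sees its own ranking.

The automatic cut-point is a chord-distance knee: for the sorted gains
v_1 ≥ … ≥ v_n, draw the chord from (1, v_1) to (n, v_n) and retain k SNPs
where k is the index of the point farthest from the chord (equivalently,
argmax |v_i − chord(i)|, since the chord's angle is constant across
points). Ties break toward the smallest index, so constant or perfectly
linear curves retain a single SNP. The distance is deliberately unsigned:
empirical IG curves have a steep informative head and a long flat noise
tail, which places the whole curve *below* its chord; an above-chord-only
rule would degenerate to k = 1 on exactly the curves that matter. The
statistic is scale-invariant in the gain values.

## SVM stage

The classifier is a C-SVM (scikit-learn `SVC`, one-vs-one multiclass) with
linear kernel k(x, x′) = xᵀx′ or RBF kernel k(x, x′) = exp(−γ‖x − x′‖²).
Genotype codes enter as raw {0, 1, 2} values — no scaling is applied by
default, since the codes already share one scale. Hyperparameters come
from an exhaustive grid over log10-spaced values: 13 C values (1e-6 …
1e6) and, for RBF, 21 γ values (1e-10 … 1e10), scored by stratified
k-fold cross-validation (default five folds) with a seeded fold
assignment. Exact CV-accuracy ties break toward smaller C, then smaller
γ; duplicate grid entries are collapsed. Accuracy is always the overall
fraction correct. If the smallest class has fewer members than folds, the
fold count shrinks (minimum 2) with a warning, or errors if configured
strictly.

The GA fitness is the cross-validated accuracy on the *sub-training* set
restricted to the masked columns (the sub-test side of each inner split is
reserved; CV on the sub-training set is the fitness signal). The final
evaluation tunes on the full outer training set, refits the winning
configuration, and scores the untouched outer test set.

## Genetic algorithms

Both GA variants share: populations of 30 bit masks over the
elbow-retained SNPs, initial bits set independently with probability
`init_p` (default 0.5), roulette-wheel parent selection (uniform when all
fitnesses tie; the second parent is always distinct from the first),
multi-point crossover at rate P_c = 0.8 with two sorted random cut points
(a count the published description leaves open as "multi-point"), a fixed
cap of 10 generations, and elitist replacement of the merged
parent+offspring pool. All-zero masks are repaired by setting one random
bit, because SVM fitness is undefined on zero features.

The variants differ only in mutation:

* **conventional** — each bit flips independently with probability P_m.
  The flip is symmetric, so mutation cannot move the expected selected
  fraction: subsets stay near half of the candidates regardless of P_m.
* **modified** — each position is chosen for mutation with probability
  P_m, and a chosen position is *overwritten* by 1 when a fresh uniform
  draw r satisfies r ≤ P_m, by 0 otherwise. P_m thus plays a dual role:
  mutation intensity and the density target. Repeated application drives
  the selected fraction to the fixed point of x → (1−P_m)x + P_m², which
  is P_m itself, so subset size is steerable; P_m = 0.9 is the default
  used by the pipeline. This dual-role reading reproduces the documented
  qualitative behaviours (insensitivity of small P_m values, larger and
  better subsets at P_m = 0.9) and is the one implemented.

Replacement keeps the fittest `pop_size` individuals of parents plus
offspring, with exact fitness ties resolved in favour of offspring. The
tie rule matters more than it looks: once CV accuracy saturates (common on
well-separated breeds) almost every comparison is a tie, and a
parent-wins or fewest-features tie-break freezes the population at its
initial composition, silencing exactly the size pressure the modified
mutation exists to exert. Offspring-wins preserves elitism — a strictly
fitter parent always survives — and the best fitness in the population is
non-decreasing across generations, which is asserted on every run.
`evolve` returns the final population leader (which carries the best-ever
fitness under elitist replacement) plus a per-generation best/mean log for
convergence plots. Every offspring is mutated position-wise; whether the
original experiments mutated only a fraction of the population per
generation is unstated. A mask-keyed fitness cache avoids re-evaluating
duplicate masks; it changes no result, only cost.

## Frequency feature selection

The r per-sub-split selections (per kernel) are reduced to occurrence
counts; features with count ≥ t survive. t = 1 gives the union, t = r the
intersection, and the survivor set shrinks monotonically in t. The default
threshold is t = 9 of r = 10 (the tuned value of the original study; the
strong-divergence validation runs use t = 7). Thresholding is applied per
kernel and the two survivor sets are then unioned — that ordering follows
the published description of the final combination step; pooling both
kernels' runs before thresholding is available behind
`PipelineConfig.pool_kernel_counts` since the published pseudocode does
not settle the point.

## Method comparison statistics

The one-way ANOVA across methods is reconstructed from per-group
summaries: SS_between = Σ nᵢ(x̄ᵢ − x̄)², SS_within = Σ (nᵢ−1)sᵢ², F =
MS_between/MS_within with (k−1, N−k) degrees of freedom and a p-value from
the F survival function. With the true group summaries this is exactly
the raw-data ANOVA (tested against `scipy.stats.f_oneway` and the two-group
t² identity). Zero within-group variance is handled explicitly (F = 0 or
∞). Percentages and table-style summaries are rounded to two decimals.
MAF is min(p, 1−p) with p = mean(code)/2 on imputed columns; the
leave-one-SNP-out scan re-evaluates the final panel with each SNP removed
and reports each SNP's MAF alongside, flagging SNPs whose removal costs
accuracy.

Note that `IG+GA+FFS` (conventional GA before the consensus) is exposed
even though it characteristically selects almost nothing: conventional-GA
masks are near-random halves, so per-feature counts rarely reach a high
threshold. That failure is part of the method comparison, not a bug.

## Synthetic data

`synthetic_data.generate` emulates a multi-breed SNP panel. Neutral SNPs
share one ancestral alternate-allele frequency p₀ ~ Uniform(0.05, 0.95)
across breeds. Informative SNPs draw per-breed frequencies from a
Balding–Nichols Beta distribution with mean p₀ and concentration
(1−F)/F, where F = `divergence` ∈ (0, 1); higher divergence pushes breed
frequencies toward fixation at 0 or 1. Genotypes are Binomial(2, p_breed)
— Hardy–Weinberg within breed, no linkage disequilibrium, no admixture,
no pedigree structure. Missingness is completely at random at
`missing_rate`. Everything is a pure function of the spec, including its
seed.

One guard applies to planted SNPs: a Balding–Nichols draw that fixes the
*same* allele in every breed (all per-breed frequencies above 0.95 or all
below 0.05) is redrawn, up to 100 attempts. At F = 0.9 roughly a third of
raw draws are such — a SNP fixed identically everywhere carries no breed
information, and labelling it "informative" would make the ground truth
unrecoverable by construction. At low divergence the draws concentrate
near p₀ and the guard never triggers, so the
informative-indistinguishable-from-neutral limit is preserved.

Canned fixtures: `tiny` (3 breeds x 10, 60 SNPs, 6 planted, divergence
0.8) for unit tests, `null` (no planted SNPs) for chance-level checks, and
`strong` (4 breeds x 30, 2,000 SNPs, 50 planted, divergence 0.9) for
parameter recovery.

What passing on synthetic data shows — and does not. Recovery of planted
SNPs at high divergence demonstrates that the ranking, the GA, and the
consensus interact as designed; it does not certify performance on real
panels, where informative SNPs are linked, effects are weaker and
correlated, breeds are unbalanced, and missingness is informative. The
simulator deliberately omits those features.

## Problem sizes and run times

Default test-suite and acceptance runs use the `strong` fixture scale (120
samples x 2,000 SNPs), 3-fold CV inside the GA fitness with a single SVM
configuration per kernel (linear C = 1; RBF C = 10, γ = 0.01), and reduced
final grids (4 C values x 3 γ values, 3-fold). These sizes are the
package's chosen desk-scale defaults; the full 13 x 21 grids and 5-fold CV
remain the library defaults for real analyses. GA hyperparameters are
never scaled down: population 30, P_c = 0.8, P_m = 0.9, 10 generations.

## Known limitations

* The elbow cut assumes a monotone score curve with a single dominant
  knee; multi-plateau curves get a defensible but single cut.
* Grid-search tie-breaking (smaller C, then γ) is deterministic but
  arbitrary among genuinely equivalent optima.
* CV-accuracy fitness is quantized by fold sizes; on tiny sub-splits the
  GA sees a coarse, plateau-heavy landscape and relies on the mutation
  pressure rather than selection gradients.
* The ANOVA-from-summary reproduces a raw-data ANOVA only as faithfully as
  the summaries themselves; summaries rounded to two decimals propagate
  an O(0.01 x Σsᵢ) uncertainty into the sums of squares.
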