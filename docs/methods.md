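# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic community does and does not emulate, and the
problem sizes the shipped tests and scripts run at.

## Synthetic community model

All strains descend from one random ancestor genome (i.i.d. nucleotides at a
configurable GC, default 0.6; non-overlapping genes packed uniformly at
random). Divergence is **substitution-only on the core backbone**: a lineage
founder is derived from the ancestor at rate *b/2* and members from the
founder at rate *w/2*, so expected pairwise divergence is ≈ *b* between
lineages and ≈ *w* within (defaults 8% and 0.8%, giving within-lineage ANI
≈ 99.2% and between ≈ 92%). Insertions and deletions are confined to whole
accessory genes: per strain, a few random ancestral genes are deleted and a
few private genes (novel orthogroups) appended; planted marker genes share
one master sequence per feature, copied into every carrier strain with
per-strain substitutions so the copies are homologous but distinguishable.
Because every genome stays colinear with the ancestor, the **true ANI of any
pair is an exact integer computation** over the shared core (positions where
the recorded substitution sets differ), which serves as the oracle for the
k-mer estimator. The community constructor validates the realized ANI
against the configured within/between thresholds and refuses infeasible
settings.

Abundances follow a log-normal model: per sample and strain, a baseline
weight exp(N(μ, σ)) is multiplied by 2^(compartment effect) in endosphere
samples and 2^(host effect), then renormalized to proportions. Reads are
single-end, fixed length (default 150 bp), drawn uniformly along the chosen
strain's genome, with i.i.d. substitution errors (default 0.5%) and an
optional fraction of reads from a host decoy sequence. Read names carry
`strain=`/`pos=`/`host=` provenance tags, making assignment accuracy and
host-filter recall directly measurable. Each operation consumes its own
spawned seed, so identical (config, seed) pairs are byte-identical, including
the gzip FASTQ output (fixed mtime).

**Noise default.** σ = 0.35 (natural log; replicate CV ≈ 36%). This was set
by a power analysis of the designed recovery experiment: the compartment
contrast at n = 7/8 has standard error ≈ 0.747·σ on the log₂ scale, plus a
residual compositional attenuation of ~0.15 log₂ units that TMM cannot fully
remove with 28 features; recovering a +2 log₂ effect within ±0.8 in ≥90% of
replicate studies requires σ ≲ 0.35. Larger σ (0.5+) is plausible for field
data but makes that specific effect size unrecoverable at this n — a
statement about power, not about the estimator.

What the generator does **not** emulate: indel/quality-score error profiles,
paired-end fragment geometry, strand sampling (reads are forward-strand),
plasmids, HGT, genome rearrangement, and realistic (megabase) genome sizes.
Passing tests therefore demonstrate correctness of the statistical machinery
and the counting semantics under the stated model, not robustness to, e.g.,
repeat-rich real genomes or adapter artifacts.

## k-mer ANI

The query genome is cut into non-overlapping fragments (default 3 kb,
mirroring fragment-mapping ANI tools). For each fragment we compute the
containment *c* = |fragment k-mers ∩ reference k-mer set| / |fragment
k-mers| (k = 16). Under uniform substitution at rate *p*, E[*c*] ≈ (1−p)^k,
so the Mash relation gives distance d = −ln(c)/k and per-fragment identity
100·c^(1/k) = 100·exp(−d), which is exact in expectation (the first-order
form 100·(1−d) is biased by ~0.5 points at 10% divergence). Fragments whose
equal-size Jaccard equivalent J = c/(2−c) falls below a mapping floor
(default 0.01) are discarded as non-homologous; if no fragment passes, the
pair has no detectable orthologous fraction and an error is raised (random
unrelated sequences behave this way). The two directed estimates are
averaged, so the matrix is symmetric by construction.

Accuracy: on substitution-only pairs the estimator tracks the exact Hamming
identity within ±0.5 percentage points across 0–10% divergence. Accessory
content (deleted/inserted genes) biases estimates slightly downward — on the
28-strain study genomes (3–5% accessory) the worst-case error is ≈ 0.6
points — because fragments straddling accessory boundaries keep partial
containment. This mirrors the behavior of alignment-fraction-based ANI tools
and is far inside the within/between lineage gap the clustering uses.

Lineages are single-linkage connected components of the ANI ≥ τ graph
(τ = 97 default). Single linkage is the least-assumption reading of
"grouping at a threshold"; the clustering function is pure and any other
criterion can be swapped in by the caller. Lineage ids are deterministic
(lexicographically smallest member), and the generator uses the same
convention so partition recovery can be asserted as dict equality. Raising τ
can only refine the partition (tested property).

## Read quantification

Pseudo-mapping by exact k-mer scoring (k = 31): a read's score against a
strain is the number of its k-mers present in that strain's k-mer index; all
strains achieving the maximal score ≥ 25% of the read's k-mers form the best
set. Unique mode discards |best set| > 1 (tie) reads — ties are exactly the
reads from segments identical across strains, which is the double-counting
the policy exists to prevent; fractional mode assigns weight 1/|best set| to
each member. The read position is the leftmost anchoring k-mer match
projected back to the read start. Implementation detail: all strains' k-mer
sets are merged into one sorted array with per-strain ownership bitmasks, so
membership is a single vectorized binary search per read batch.

Host filtering removes reads whose k-mer match fraction against the host
decoy is ≥ 0.5; with error-free reads this removes decoy reads exactly, with
0.5% errors a small tail (reads carrying ≥2 well-spaced errors) leaks
through and is subsequently dropped by the community score floor.

Gene-level counting is unstranded, ≥1 bp overlap, largest overlap wins, ties
dropped and logged (genes within a strain never overlap by construction, so
a read meets at most a handful of consecutive genes). Orthogroup counts sum
member genes across strains; optional per-copy normalization divides by the
orthogroup's total gene-copy number across all community genomes (a fixed
per-feature constant — the alternative, copies among detected strains only,
would make the denominator sample-dependent and is left to the caller).

TMM follows the standard trimmed-mean-of-M-values recipe: reference sample =
the one whose upper-quartile/library ratio is closest to the mean; M and A
over doubly-positive features; 30% trim on each M tail, 5% on each A tail;
inverse-delta-method precision weights; factors rescaled to geometric mean 1.
The implementation agrees with the reference edgeR implementation to 1e-6 on
random matrices (cross-checked in the test suite via Rscript).

## Strain enrichment (voom + moderated t)

logCPM = log₂((count + 0.5)/(lib·factor + 1)·10⁶). Per-feature residual sd
comes from OLS on the design (intercept + compartment indicator + host
indicator [+ interaction]); sqrt(sd) is smoothed against mean log count by
lowess (span 0.5, 2 robustness iterations) and the trend value at each
fitted observation is raised to the −4th power to give observation weights,
clipped to [1e-6, 1e6]. A residual-sd floor of 1e-4 guards degenerate
constant features. The moderated fit runs per-feature weighted least squares
(vectorized over features via stacked normal equations), then shrinks
residual variances toward a scaled-inverse-χ² prior whose (d₀, s₀²) are
moment-matched on log variances (digamma/trigamma matching, Newton inversion
of the trigamma); the moderated t uses d₀ + d_residual degrees of freedom.
The d₀ = 0 and d₀ → ∞ limits reproduce the ordinary t and the pooled z
exactly (tested). BH correction is Benjamini–Hochberg over all features.

Sign convention everywhere: positive log₂FC = endosphere-enriched (the
design codes endosphere as 1). The reported fold change defaults to the
fitted model coefficient; a CPM-ratio variant (log₂ of compartment mean CPM
ratio with +0.5 stabilizer) is available since summary fold changes are
sometimes reported that way.

Strategy labels are an explicit rule at α = 0.05 and abundance quantile 0.5
(the source classes are qualitative, so the thresholds are configuration,
not inference): significant positive + endosphere CPM ≥ quantile → strong
colonizer; significant positive below it → niche specialist; non-significant
but above the quantile in both compartments → generalist; significant
negative → rhizosphere-associated; otherwise unclassified.

## KO rule

Presence of a KO in a lineage is 1 if any member genome has ≥1 gene with
that KO. Enrichment requires ≥ min_endo endosphere-associated lineages
(default 2) and ≤ max_non non-endosphere lineages (default 4); the
thresholds are taken literally as "at least"/"no more than" and the group
sizes derive from the lineage map rather than being hard-coded. Frequencies
are reported as the proportion of lineages in each group containing the KO.
The rule is verified against KO-by-KO enumeration and is monotone in both
thresholds.

## Functional diversity

Richness counts features with CPM > 0; Shannon H uses natural log (the
dominant ecology convention; base is a parameter). Group comparisons use the
two-sided Wilcoxon rank-sum (exact when combined n ≤ 20 without ties,
tie-corrected normal approximation otherwise) and one-way ANOVA. Bray–Curtis
is Σ|x−y|/Σ(x+y) between sample columns.

NMDS minimizes Kruskal stress-1 = sqrt(Σ(d̂−d)²/Σd²) by alternating isotonic
regression of disparities on the dissimilarity ranks with Guttman (SMACOF)
configuration updates; the first start is a classical-scaling configuration,
the rest random; an iteration that would raise stress stops the start (so
the recorded trace is non-increasing), tolerance 1e-6, defaults 20 starts ×
300 iterations, best start wins; non-convergence returns the best
configuration with a flag rather than failing.

PERMANOVA Gower-centers the squared distance matrix and partitions
tr(G) by sequential (type-I) projections onto nested design subspaces, so
R² terms plus residual sum to exactly 1; pseudo-F per term; the null
permutes sample labels freely (no strata — none are implied by the design;
a strata option would be the natural extension), p = (1 + #{F_perm ≥
F_obs})/(n_perm + 1), with exhaustive enumeration available for small n.
Term order (compartment before host) is explicit configuration. The F
statistic matches scikit-bio's PERMANOVA on one-factor designs and the
permutation p matches exhaustive enumeration at n = 6 (both tested).

## Consensus differential abundance

*Negative-binomial Wald*: size factors by median-of-ratios against the
geometric-mean pseudo-reference (features with any zero excluded);
dispersions by method of moments on normalized counts, clipped to
[1e-8, 10], shrunk 50/50 toward a fitted a₀ + a₁/mean trend; NB2 GLM with
log link and size-factor offsets by IRLS (vectorized across features); Wald
z on the compartment contrast against the normal reference — with the
trend-shrunken moment dispersions this is well calibrated at n = 15 (type-I
≈ 0.045); an optional t-reference with residual df is provided for users who
want extra conservatism. All-zero features get p = 1 and a flag.

*voom route*: identical code path to strain enrichment (TMM + voom +
moderated t); per-copy (fractional) counts are rounded to pseudo-counts
first and the rounding is recorded.

*CSS + zero-inflation*: per-sample scale = sum of counts at or below the
median of that sample's nonzero counts (quantile configurable); normalized
value log₂(count/scale·1000 + 1); a two-component EM assigns each zero a
posterior probability of being structural (point mass at zero, prior
logistic in standardized log library size) versus arising from the Gaussian
abundance component (feature-specific mean, pooled variance); EM capped at
100 iterations, tolerance 1e-6 on the complete-data log-likelihood,
non-convergence falls back to unit weights with a warning. Weights
(1 − P(structural), floored at 1e-4 to keep the WLS full-rank) feed the same
moderated-t machinery. The EM separates structural from sampling zeros
reliably when the two classes are identifiable (rare features produce
detection dropouts, well-detected features produce structural absences);
zeros of features whose mean sits near the detection limit are inherently
ambiguous and no classifier resolves them.

*Consensus*: a feature qualifies iff q < α in all three methods **and** the
fold-change sign agrees across methods and matches the requested direction
(endosphere = positive). Direction consistency is the default and can be
switched off. The consensus is conservative by construction: in the planted
simulations it holds the false-discovery proportion near zero at sensitivity
≈ 1 for 4× effects at n = 7/8.

Per-host analysis reruns the voom route within each host's samples and
reports per-host significant sets, their intersection, disjoint
(UpSet-style) cardinalities, and presence/absence detection sets per
host × compartment. The framework intersection keeps KOs that annotate ≥1
consensus orthogroup and are simultaneously in the lineage-level enriched
KO set.

## Problem sizes

The shipped study (analysis/ scripts) uses 28 strains × 100 kb genomes, 15
samples × 20k reads; the default pipeline configuration uses 10 strains ×
0.5 Mb × 15 samples × 50k reads; recovery and calibration experiments use
50 seeds (strain recovery at 28 strains), 20 seeds (consensus error control
at 330 features), 200 simulations (PERMANOVA null at n_perm = 199), and 100
random matrices (KO rule enumeration). Genome sizes are desk-scale stand-ins
for real multi-megabase genomes — every algorithm is size-agnostic, but the
exact-alignment oracle and the all-pairs true-ANI bookkeeping are only meant
for genomes in the tens-of-kilobase to megabase range.

## Known limitations

- Pseudo-mapping by exact k-mer match has no mismatch tolerance within a
  k-mer; at high error rates (>2–3%) scores against the true strain decay
  and the unique/fractional tie semantics blur. The generator's error rates
  (≤0.5%) are far from this regime.
- The three DA procedures are calibrated reimplementations, not ports;
  users comparing against DESeq2/limma/metagenomeSeq outputs should expect
  agreement in calls and ordering, not in decimals.
- PERMANOVA uses free permutation; designs needing restricted permutation
  (repeated measures, blocks) are out of scope.
- The KO rule treats lineages as exchangeable units and ignores phylogenetic
  non-independence beyond the lineage grouping itself.
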