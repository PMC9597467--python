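# Methods

## Data model and units

The unit of observation is one destructively sampled plant, separated
into leaf, stem and tuber. Weights are grams per plant; tissue N/P/K
concentrations are mg per g dry matter (assay-native scale); uptakes are
reported in g plant⁻¹, so the uptake sum carries a /1000 conversion.
For the tuber, the record stores total fresh weight and total dry
weight; percent dry matter is 100 × dry/fresh, and the total dry tuber
weight equals total fresh weight × DM/100 by construction. Validation
enforces dry ≤ fresh, non-negative weights, concentrations finite and
< 1000 mg g⁻¹, one entry per plant × organ, and unique
(genotype, block, treatment, plant) keys; CSV rows violating these are
reported with their 1-based data-row numbers.

Per-plant nutrient supply under +F is F = rate (kg ha⁻¹) × 1000 /
density (plants ha⁻¹). The default configuration (90/50/75 kg ha⁻¹ at
20,000 plants ha⁻¹) gives 4.5/2.5/3.75 g plant⁻¹ for N/P/K. The rate
and density are trial constants; the division into a per-plant supply
is this package's convention for putting ANR's numerator and
denominator on the same per-plant scale.

## Index computation

All indices are computed from full-precision genotype × treatment means
and rounded only at report time (1 d.p. for weights and PD, 2 d.p. for
SFSI, matching conventional reporting). Grand means are unweighted means
of the genotype means; with balanced data this equals the plant-level
mean, and a plant-weighted alternative is available for unbalanced data.
The identity SFSI × FII = PD/100 holds exactly and is asserted in tests.

ANR and PE are computed per genotype from the genotype × treatment mean
uptakes and dry tuber weights — the formulas' paired-environment
structure — not from per-plant pairs, which do not exist in a
destructive harvest. PE is flagged undefined (missing value, never a
silent zero or an exception) when |U_tF − U_tN| ≤ eps, default
eps = 1e-6 g; near-zero uptake differences are realistic for
unresponsive genotypes. Uncertainty for ANR/PE comes from a seeded
block-level bootstrap (default 1000 resamples): blocks are resampled
with replacement and both treatment arms of a block enter together,
preserving the pairing.

Susceptibility classification: susceptible iff SFSI > 1; SFSI exactly 1
is classified tolerant (strict inequality is the conventional
criterion). The per-genotype t-test significance is carried as an
annotation beside the class, not as part of the criterion.

Stems carry no concentrations in the reference design (only leaf and
tuber tissue were assayed); the default "zero" absent-organ policy lets
them contribute nothing to uptake, and a "strict" policy turns missing
concentrations into errors. Whether stem nutrients belong in total
uptake is therefore an explicit switch rather than a hidden assumption;
the default excludes them.

## Trial statistics

- Treatment contrasts: two-sample t-test per genotype on plant values,
  Welch (unequal variances) by default since the variant is not
  otherwise determined; pooled-variance available by flag. Two
  completely identical arms return t = 0, p = 1.
- Tukey HSD among genotypes within a treatment, on scipy's studentized
  range tests, summarized by an insert-and-absorb compact letter
  display: groups sorted by descending mean (ties broken by label for
  determinism), every significant pair splits the letter columns
  containing both, subset columns are absorbed. The display is provably
  consistent with its p-matrix: sharing a letter ⇔ pairwise p ≥ α.
- Pearson correlation with the two-sided t-transform p.
- Split-plot ANOVA computed on subplot means (plants within a subplot
  are subsamples): blocks, treatment tested against the block ×
  treatment (main-plot) error, genotype and genotype × treatment tested
  against the subplot residual. A classical two-stratum ANOVA is used
  deliberately instead of a REML mixed model: with balanced data the
  inferential conclusions coincide and every sum of squares is
  specifiable in closed form (and asserted additive in tests). Wald
  chi-square statistics from specific mixed-model software are
  implementation-dependent and are not reproduced. Tukey HSD already
  controls its pairwise family; no additional correction is applied
  across traits.

## Synthetic trial generator

The generator emulates the reference design: split-plot randomized
block, fertility on main plots, 6 genotypes on subplots, 4 blocks,
3 sampled plants per subplot (144 plants). Per genotype the +F dry
tuber (and shoot) mean is a base parameter and the non-F mean is
base × (1 − responsiveness), so responsiveness is exactly the target
PD/100. Noise is multiplicative lognormal at three levels — main plot,
subplot, plant — each mean-corrected to leave expectations at the
configured targets. Default CVs are 0.10 (main plot), 0.10 (subplot)
and 0.20 (plant): plant-to-plant variation dominates in tuber crops,
and these levels give per-cell dispersions under which the weaker
genotype contrasts are non-significant while the strong responders are
detected — the qualitative signature of the reference trial.
Concentrations are drawn lognormally (CV 0.05) around organ × nutrient
means with a multiplicative +F response; DM% gets additive Gaussian
noise (SD 1 pp, clipped to 5–65%).

Calibration: the packaged default reproduces, in expectation, the
published genotype × treatment means of dry shoot weight, dry tuber
weight, tuber DM% and N/P/K uptakes (`yamnue.calibration`). Leaf
concentrations are fixed at 25/2.5/20 mg g⁻¹ N/P/K — within the range
reported for yam leaf tissue — and each genotype's tuber concentrations
and +F multipliers are then solved exactly from its uptake targets.
Free parameters the reference trial does not report, chosen once and
documented here: leaf:stem split of shoot dry weight 0.55:0.45, shoot
dry-matter fraction 0.25 (used only to back out plausible fresh
weights), and the plant-level variance components above. The calibrated
means are treated as approximate descriptions of the real trial, not as
ground truth of the underlying field process.

What the generator does not emulate: spatial field trends, emergence
variation, missing plants/unbalanced cells, measurement error distinct
from biological variation, and any correlation between tissue
concentration and plant size. Passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to those real-data features.

## Recovery experiments and their calibration

`recovery_experiment` simulates n replicates (independent substreams
spawned from the config seed), runs the full pipeline on each, and
reports bias and RMSE of SFSI, ANR and PE against the noise-free truth
(defined by running the same estimators on a zero-variance draw, so
"truth" and estimate share conventions). It also records the
per-replicate Spearman correlation between estimated and true SFSI
ranks. At the default noise a single 4-block trial recovers the
six-genotype SFSI ranking only approximately (adjacent genotypes with
SFSI gaps of ~0.15 swap readily); the replicate-averaged estimates
recover it essentially perfectly, which is what the aggregate rank
check asserts.

The split-plot ANOVA null calibration simulates zero-effect trials
(all genotypes identical, responsiveness 0) and checks the uniformity
of the treatment, genotype and interaction p-values over 500 seeds
(Kolmogorov–Smirnov at α = 0.01). The check runs on the raw trait
scale: with multiplicative lognormal noise normal-theory p-values are
only asymptotically uniform, and the observed deviations at these CVs
are well inside the KS tolerance.

Problem sizes used by the test suite — 500-seed null calibration,
200-replicate recovery at default noise, 100 replicates at 64 blocks
for the consistency check, 1000 bootstrap resamples by default — were
chosen so Monte-Carlo error is small against each assertion's margin.

## Numerical choices and degenerate inputs

- Percent difference and SFSI require x̄_hf > 0; FII requires Ȳ_hf > 0
  and SFSI additionally FII ≠ 0 (no stress differential): violations
  raise a typed undefined-index error.
- PE's eps threshold as above; bootstrap percentiles drop undefined
  draws and report their count.
- CSV I/O is lossless: floats are written at full precision and parsed
  with round-trip precision, so read(write(x)) == x exactly and a fixed
  seed yields byte-identical files.
- Letter-display ties in group means are broken by label order;
  all-identical data yield a single shared letter.

## Known limitations

Exact reproduction of published ANR/PE bar values is impossible from
printed summary data: they were computed from unrounded uptakes, while
uptake means are printed at 0.1 g plant⁻¹, which alone moves ANR-N by
up to ±2.2 percentage points. The indices here match the published
endpoints within that rounding envelope. The ANOVA replaces, by
design, mixed-model Wald statistics; the bootstrap assumes blocks are
exchangeable; and the generator's variance components are assumptions,
not estimates from the (undeposited) raw data.
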