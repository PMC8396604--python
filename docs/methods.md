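# Methods

This note documents the models, parameter choices and numerical
conventions behind `chptools`, and what its synthetic-data tests do and do
not establish about real data.

## Partner triage

The triage score is the relative peptide difference between the bait and
IgG co-IPs. Two readings of "relative difference" are defensible —
relative to the bait, (O − I)/O, or relative to the control, (O − I)/I —
and both are consistent with every bundled peptide-count row at the >50%
threshold (the bait form is equivalent to O > 2I, the control form to
O > 1.5I). The bait-relative form is the default because it reads most
naturally as a fraction of the bait signal and is bounded in [0, 1]; the
control-relative form is available via `mode="control"`. Exclusive
detection (I = 0) scores 1 (or +∞ in control mode), so bait-only proteins
always clear the threshold. The score is undefined (None) when O = 0:
absence from the bait co-IP is representable, not an error.

Category semantics:

* `unique` and `selected` are disjoint by construction: `selected`
  requires I ≥ 1. This is forced by the category arithmetic of summary
  tables in this design, where unique counts exceed selected counts, which
  would be impossible if exclusivity implied selection.
* `unique_small` uses an inclusive 25 kDa bound and may co-occur with
  `unique`, so per-category counts can sum to more than the partner total;
  the identity `total = |unique| + |selected| + |unique_small| −
  |unique ∩ unique_small|` is property-tested.
* Peptide counts are treated as distinct peptide identifications, not
  PSMs; they enter the rules as plain integers.
* Molecular masses come from an annotation table when given, else from the
  sequence as the sum of average (not monoisotopic) residue masses plus
  one water, delegated to Biopython. An explicit mass wins over a
  sequence.

Replicate consensus is the strict intersection of member sets. A consensus
member's flags are reported as the union of the flags it earned across
replicates: a protein unique in one replicate and selected in another is a
partner in both, and discarding either flag would misrepresent the
evidence. Cross-structure comparison re-filters each structure's records
with the high-confidence rule (O ≥ 3 and rel∆ > 0.5, exclusivity counting
as 100%), intersects over a required structure subset, and reports the
overlap with any further structures; proteins without counts in a
structure carry 0/0 there.

## DE concordance

Fold changes are ratios of the supplied per-condition mean reads with the
negative-reciprocal convention for decreases, reported at two significant
figures. Zero means produce sentinels: control = 0 → +∞ ("infinite"
induction), knockdown = 0 → −∞, both zero → NaN. A caveat documented here
deliberately: upstream DE engines normalise per sample before averaging,
so a minority of published fold values are not ratios of the printed
means; the bundled tables keep the printed value in a separate
`reported_fold` column and only ratio-consistent rows are asserted in
tests. One bundled prose-level knockdown percentage (fourth-ventricle
conditional, 6898 → 4169 mean reads) rounds to 40% by the formula here
while the source reports 39%; it is not asserted.

Adjusted p-values are consumed, never computed: the upstream DE test is
facility-specific and out of scope, and the synthetic generator assigns
p-adj directly. Significance filtering is strict (p-adj < α, default
0.05); genes with missing p-adj or no direction (equal means) are
excluded. Consensus membership requires significance with a consistent
direction in every required comparison; significant but direction-mixed
genes are reported separately as discordant. The expression floor used to
build enrichment backgrounds keeps genes with more than 10 mean reads in
at least one condition of at least one table.

## Enrichment

The statistic is the plain upper-tail hypergeometric probability
P[X ≥ k] (one-sided Fisher), not the modified EASE-style score used by
some web tools, so published enrichment p-values from such tools are not
comparison targets. Annotations are intersected with the background at
construction and empty terms dropped, which keeps every stored term a
subset of the background; query genes outside the background are dropped
with a warning. Benjamini–Hochberg is delegated to statsmodels. The
default minimum term size is 2: singleton terms are almost always
annotation noise at desk scale.

## Isoform usage

Isoform fractions pool replicates by summing counts before dividing by the
gene total — the simplest reading of "% of total isoforms" — with a
per-replicate-mean mode as configuration. The switch test replaces a
GLM-based differential-transcript-usage fit with a two-proportion z-test
on the isoform's share of the pooled gene counts in the two conditions,
falling back to Fisher's exact test on the rounded 2×2 table when any
expected count is below 5. Fisher's conditional exact test was chosen as
the small-count fallback because it is the standard exact test for
comparing two proportions. The fallback and the z-test agree closely in
the regime where both apply. Degenerate isoforms (observed in neither or
all counts) get p = 1. Switch calls require both |dIF| ≥ 0.15 (inclusive)
and BH-adjusted p < 0.05; the usage cutoff is evaluated per isoform.

Because counts are pooled, the test ignores between-replicate dispersion
and will be anticonservative on strongly overdispersed real data; the
generator's Dirichlet option exists to probe exactly that. Single-isoform
genes are skipped (their dIF is identically 0), as are genes absent from
one condition (warned).

## qPCR

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the arithmetic
mean ΔCt of the calibrator group (a log2-scale mean, matching comparison
to mean control expression); fold = 2^−ΔΔCt. Consequently the calibrator
group's geometric — not arithmetic — mean fold is exactly 1, and all folds
are invariant to plate-wide Ct offsets. Technical replicates are averaged
on the Ct scale before any normalisation (averaging folds instead would
weight cycles exponentially). Group comparison is a two-sample t-test on
fold values, reported only when both groups have n ≥ 2. No
amplification-efficiency correction is applied.

## Synthetic data

The generators emulate the three input classes at desk scale with standard
count models, chosen because the emulated pipelines publish no noise
model:

* **co-IP** — Poisson peptide counts per replicate. Defaults: 60 true
  partners (bait mean 8, control 0), 30 small bait-exclusive proteins
  (bait mean 1.5, masses uniform on 8–24 kDa), 300 symmetric contaminants
  (mean 6 in both co-IPs), 3 replicates; other masses log-normal around
  45 kDa. The 60/3 scale mirrors the consensus-partner scale of the ChP
  experiment the toolkit targets. `noise_free=True` fixes counts at the
  rounded class means, making triage recovery exact — the basis of the
  sensitivity = specificity = 1 test.
* **DE** — 2000 genes, log-normal baseline means (log-mean 5, log-sd 1.5,
  i.e. median ≈ 150 reads), planted consensus of 42 up / 34 down (the
  scale of the global three-comparison signature), 100 extra
  single-comparison DE genes per comparison, |log2 fold| ~ N(1.5, 0.5)
  truncated at 0.5. p-adj is drawn below 0.9·α for planted genes and on
  [α, 1) for nulls, so consensus recovery is exact by construction — the
  generator tests the set logic, not a DE test.
* **isoforms** — 20 genes × 2 isoforms, 1000 reads per gene per condition
  split over 2 replicates, 4 switch genes with planted dIF 0.30
  (usage 0.5 ∓ dIF/2 → 0.5 ± dIF/2), multinomial counts, optional
  Dirichlet overdispersion, and a deterministic expected-count mode.

All generators are pure functions of their spec including its seed.
Passing recovery tests on these models shows the estimators and set
algebra are correct under clean, correctly-specified noise; it does not
establish robustness to the features of real data the generators omit —
correlated replicates, overdispersion beyond the optional Dirichlet,
compositional MS biases, batch structure or p-value miscalibration.

## Problem sizes and determinism

Tests and the acceptance script run on the bundled 14-protein table and
on generator defaults (2000-gene DE tables; 200 seeded simulations of the
20-gene isoform experiment for the power and false-positive checks), with
every stochastic step seeded through `numpy.random.default_rng`.
Hypothesis property tests run derandomised.
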