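# Methods

## Data model

An experiment is a set of **multiplexes**, each an ordered pool of 2–8
chromatographic fractions from one separation dimension (SEC or HIC),
measured together under isobaric (iTRAQ) labels. A protein's record in a
multiplex is a relative-abundance vector over the multiplex's fractions plus
a unique-peptide count. A protein is *detected* in a multiplex iff such a
record exists; the upstream peptide-confidence filtering that decides what
counts as a confident identification is assumed already applied and is not
re-derived here. Fraction identifiers are opaque strings ordered by their
declaration order in the design table — no numeric parsing, so 0- versus
1-based numbering cannot introduce off-by-one errors. Joint fractions
(shared between adjacent multiplexes to stitch column-wide profiles) are
declared in the design table but deliberately *not* deduplicated when
counting a protein's observances: the multiplex is the unit of observation,
and a joint fraction genuinely appears in two measurements.

**Apex normalization** divides each (protein, multiplex) vector by its
maximum, so the apex fraction reads 1. When several fractions tie at the
maximum all of them become 1 — the tie needs no arbitration because every
downstream quantity (Pearson correlation, detection, counts) is indifferent
to which tied fraction is "the" apex. All-zero records are dropped with a
warning. The pre-normalization intensities are retained because the
correlation-eligibility rule below is defined on raw values.

**Exclusion filtering** removes ribosomal proteins and the four classic
highly abundant chaperonins (DnaK, GrpE, GroEL, GroES; DVU0811/0812/1976/1977
in *Desulfovibrio vulgaris*): their abundance makes them promiscuous
co-eluters. The default list is assembled from an `excluded` annotation
flag, a ribosomal-annotation regex, and the four named ids; datasets from
other organisms pass their own list.

## Features

Within one multiplex, the pair correlation (CC) is the Pearson correlation
of the two normalized vectors, computed only when at least one of the two
proteins has raw intensity ≥ `eligibility_intensity` (default 0.01) in at
least `eligibility_fractions` (default 3) fractions — profiles that never
rise above noise produce meaningless correlations. Constant profiles are
skipped (Pearson undefined). The per-dimension feature is the maximum CC
over that dimension's eligible shared multiplexes, −1 when there are none;
−1 rather than a neutral value because never being co-observed in a
dimension is genuine negative evidence under data-dependent acquisition.

The co-migration coefficient is implemented exactly as stated in its
defining formulation, T/(N_a+N_b) with range [0, 0.5] — half the textbook
Dice coefficient. The classic 2T/(N_a+N_b) variant is available behind
`FeatureConfig(classic_dice=True)`; a monotone classifier is insensitive to
the constant factor, so the choice is cosmetic.

Two sentinel conventions: `min_proteins` falls back to (densest multiplex's
protein count + 1) when the pair never co-elutes at CC ≥ 0.85, i.e. "never
tightly co-eluting" reads as maximally unfavorable fraction-space density;
the peptide ratio falls back to 0 for pairs sharing no multiplex (such pairs
are outside the candidate universe anyway). Sentinels enter the regression
as ordinary numbers after standardization. Whether the 0.01 eligibility
threshold refers to reporter-ratio or another raw scale is not fixed by the
method's description; it is a config knob. `min_proteins` counts proteins of
the *filtered* dataset, since excluded proteins never reach the feature
stage.

Genome-context features are ingested, never computed: a STRING-style table
of neighborhood / co-occurrence / fusion subscores rescaled to [0, 1],
defaulting to (0, 0, 0) for unlisted pairs.

`assemble_features` computes all eight features for every co-occurring pair
with per-multiplex vectorized correlation matrices; `pair_features` is the
straightforward per-pair reference path, and the test suite holds the two
(and independent brute-force oracles) equal.

## Classification and FDR

Two logistic regressions: MS-only (features 1–5) and MS+STRING (1–8).
Features are z-scaled with statistics from the training rows only; a light
fixed L2 penalty (sklearn C = 10) keeps coefficients finite on separable
folds while perturbing the fit negligibly; lbfgs makes fits deterministic.

**One-operon-out cross-validation.** Pairs sharing a protein — and in
bacteria, an operon — are not independent, so random pair-level folds leak
information. Each fold holds out one operon: its validation set is every
candidate pair touching any protein of the operon, its training set every
gold pair touching none. Proteins without operon annotation form singleton
operons. A pair spanning two operons is validated in both folds (its scores
are averaged) and trains in neither. Folds whose training set collapses to
a single class are skipped; pairs never held out in any usable fold are
excluded from prediction rather than scored optimistically.

**FDR thresholding.** At threshold t the FDR estimate is the plain
gold-count ratio N⁻(≥t)/(N⁺(≥t)+N⁻(≥t)); `threshold_for_fdr` returns the
lowest threshold attaining the target (inclusive ≥, ties all included),
maximizing predictions. The estimator applies no reweighting from the gold
class balance to the candidate universe's class balance. This is a known
limitation: it is calibrated only when gold pairs are sampled from
candidates at equal rates per class, which the synthetic generator does by
construction (below); with a gold set whose positive:negative ratio
overstates the candidate prior, the estimate is optimistic.

`select_high_confidence` exposes the high-confidence cut as an explicit
score parameter plus a kept/discarded quality-metric report; converting
"high score and enriched quality metrics" into a specific cut is a judgment
call that the package reports rather than hard-codes.

## Validation statistics

PPI fold enrichment of a pair set: the fraction of its pairs — among those
whose both members are detected — with CC ≥ 0.85 in both dimensions,
divided by the same fraction over the set of all co-occurring pairs. The
reference set's own enrichment is exactly 1 by construction. The fraction's
denominator includes detected-but-not-co-occurring pairs, so the statistic
combines the propensity to co-occur with the propensity to correlate.
Interolog mapping between species is treated as an ingested pair-translation
table, not computed.

FNR = 100 × (1 − recovered/eligible). Overlap reports carry full
union/intersection accounting plus *conditional* overlaps restricted to
pairs whose proteins are detectable by the other assay; one minus that
conditional overlap estimates the other assay's FNR, a consistency the test
suite checks on synthetic twin assays. Held-out-gold FDR and the
overlap-enrichment accuracy bound (novel sets overlapping an independent
reference k-fold less than gold positives are at most 100/k % accurate)
are pure count arithmetic, kept as explicit functions so audits are
reproducible. Percentages are returned at full precision; rounding is the
caller's display decision.

The functional-annotation (TIGR role) sharing enrichment uses an analytic
null — the probability that two distinct proteins drawn from the annotated
universe share a role, Σ_r C(n_r,2)/C(n,2) — with an optional permutation
interval for small sets.

## Synthetic experiments

The generator emulates one HIC column of 12 fractions whose every fraction
is separated on a 19-fraction SEC column. SEC multiplexes tile each SEC
column as 8 + 8 + 5 fractions with the 8th and 15th fractions joint; HIC
multiplexes tile the HIC dimension as 8 + 5 with one joint fraction at every
second SEC retention time — the two labeling schemes of the real assay at
roughly one-column scale. Defaults of 500 proteins and 60 complexes
(size 2 + Poisson(1.5), capped at 8) give ≈ 320 true co-complex pairs among
≈ 70,000 co-occurring candidates, a realistically unfavorable prior; this
scale keeps a full simulate-classify-evaluate cycle around half a minute on
one CPU.

Elution peaks are Gaussian over fraction index — the conventional
chromatographic approximation — with widths σ_SEC = 1.3 and σ_HIC = 1.0
fractions. Complex members share their complex's apex pair up to N(0, 0.35)
jitter. Protein amplitudes are lognormal (σ = 0.7); measured intensities
get multiplicative lognormal noise (σ = 0.25) independently per multiplex,
as separate MS measurements of the same fraction would. A protein is
detected in a multiplex when its peak intensity there exceeds 0.05 and it
survives a 15% per-(protein, multiplex) dropout emulating data-dependent
acquisition. Peptide counts are 1 + Poisson(6 × peak intensity, capped),
increasing with abundance. Three percent of proteins are frequent fliers
with four Gaussian peaks scattered over the fraction grid; ten proteins
carry a ribosomal annotation to exercise exclusion filtering.

Operons follow complexes with probability 0.7 (split into runs of ≤ 4);
10% of monomers pair into small random operons; the rest are singletons.
Genome-context scores are high for co-operonic pairs (Beta(8,2)
neighborhood), moderate for co-complex pairs (60% carry a Beta(4,2)
co-occurrence score), and sparse low-level noise elsewhere — elevated
context for operon/complex pairs with enough background to keep the STRING
features imperfect.

**Gold standard construction.** Positives are co-complex and negatives
cross-complex pairs, both drawn from co-occurring candidate pairs at one
common Bernoulli rate (default 0.3). Equal-rate sampling makes the gold
class balance mirror the candidate universe's, which is exactly the
condition under which the unweighted gold-count FDR estimator is calibrated;
it yields a gold negative set much larger than a manually curated one would
be, a deliberate trade of realism in size for correctness of the estimator's
premise.

What the generator does **not** emulate: spectra and ion statistics, iTRAQ
reporter-channel chemistry and ratio compression, correlated (structured)
noise across fractions, shared-peptide ambiguity, abundance-dependent
detection bias beyond the simple threshold, and multi-column replication.
Passing tests therefore demonstrate the statistical machinery — feature
behaviour, CV hygiene, FDR calibration under a representative gold sample —
not robustness to every artifact of real CF-MS data.

## Numerical choices and degenerate inputs

- Pearson correlations via `numpy.corrcoef`; zero-variance profiles are
  skipped, not scored 0.
- Exact-round-trip TSV: float columns are serialized with `repr` and parsed
  with pandas' round-trip precision, so writer→reader is bit-exact.
- The vectorized and per-pair feature paths may differ by ~1 ulp (matrix
  versus pairwise correlation evaluation order); tests compare at 1e-9.
- Thresholding uses inclusive ≥ everywhere; FDR-not-estimable (no gold pair
  above threshold) is reported as `None`, never 0.
- All randomness flows from explicit `numpy.random.default_rng(seed)`
  generators; identical configs give byte-identical artifacts.

## Known limitations

- The gold-count FDR estimator ignores the candidate prior (see above).
- Leave-operon-out CV is mildly pessimistic at small sample sizes — with
  permuted labels the held-out AUC centers slightly below 0.5 because each
  fold's training set is depleted of the held-out class pattern.
- `min_proteins`'s sentinel couples the feature's scale to the densest
  multiplex of the dataset at hand; models should not be transported across
  datasets without refitting.
- The CLI `validate` report computes enrichment against the supplied
  feature table; features must come from the same filtered dataset or the
  reference fraction will be inconsistent.
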