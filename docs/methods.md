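# Methods

This note documents the statistical procedures, the synthetic study design
used for validation, the numerical choices, and the limits of what the test
suite demonstrates.

## Screening model

The pipeline screens a samples × metabolites intensity matrix (two varieties,
time points in hours after imbibition, replicated) against a germination
phenotype.  A metabolite is a candidate when it passes all three filters:

**COR (trait correlation).** For each variety, the Pearson correlation `r`
between the metabolite's replicate-mean content and the replicate-mean
germination fraction across the informative time points (default
{6, 9, 12, 24, 36, 48} HAI; 0 and 3 HAI precede any germination signal and
are excluded).  Significance uses the classical transform
`t = r·√(n−2)/√(1−r²)` with `n−2` degrees of freedom, two-sided — identical
to R's `cor.test`.  Pass: `p < α` (default 0.05) **and** `|r| > r_min`
(default 0.8).  With n = 6 the `|r| > 0.8` condition is nearly equivalent to
the p condition (the two-sided 5% critical r at df = 4 is 0.811).  Replicate
means, not replicate-level points, are the unit of correlation: the reference
worked examples (r = 0.94 → p = 0.005; r = −0.95 → p = 0.004) reproduce
exactly at n = 6, which pins that choice.

**CV (fluctuation).** `CV = σ/μ` with the sample SD (n−1), computed by
default over the variety's 8 per-time-point means (a replicate-level basis is
available via `basis="replicates"`).  Pass: `CV > 0.30`.

**DAM (differential accumulation).** At each tested time point, a two-sided
two-sample Student's t-test (equal variance; Welch optional) on the replicate
values of the two varieties, with fold change computed from replicate means
as larger/smaller (≥ 1 with a direction flag).  A pseudo-count
`ε = 0.5 × (smallest positive value in the matrix)` guards zero means; it is
configurable, and matters only when intensities sit near the detection
floor.  p-values are Benjamini–Hochberg adjusted within each time point
across metabolites; pass: `fold change > 2` and adjusted `p < 0.05` at at
least one time point (gating on raw p is a config switch).  Degenerate
cells — zero variance in both groups — give `p = 1` for equal means and a
flagged fold-change-only decision otherwise.

**Combination.** COR and CV are computed per variety and combined by union
(a metabolite informative in either genotype is kept; intersection across
varieties is available as `combine_mode="intersection"`), then intersected
with DAM.  The intersection is always a subset of each method set, and the
per-class counts of the candidate table sum to its size — both are asserted
in tests.

Missing policy: correlations are pairwise-complete; a metabolite is dropped
from a t-test at a time point when any replicate is missing in either group;
every exclusion is logged with a reason.

## Replicate QC

Each replicate's metabolite vector is Pearson-correlated against each
sibling at the same variety × time point; the mean sibling PCC is reported
and a replicate below threshold (default 0.9) is flagged.  Flagging is
worst-first and iterative because one discordant replicate also drags down
its siblings' mean concordance: the lowest-concordance member is flagged,
concordance is recomputed among the remainder, and the step repeats.  The
0.9 default is a pragmatic choice for targeted LC–MS replicates, whose
retained sibling correlations typically sit above ~0.94; it is exposed as
`--qc-threshold`.  Removal is opt-in (`--qc-drop`) — the default run only
reports, because silent data removal is hazardous — and removal that would
empty a variety × time point is an error.

## Stage segmentation and lag

Variety × time-point profiles are replicate means per metabolite; their
Pearson correlation matrix (pairwise-complete, unit diagonal) is the object
clustered in heatmap views of germination time courses.  Stages are obtained
per variety by an **order-constrained agglomerative merge**: starting from
one segment per time point, the adjacent pair of segments with the highest
between-segment mean PCC is merged until `k` (default 3) segments remain;
ties break toward the earlier boundary.  Unlike free hierarchical
clustering, this guarantees stages are contiguous intervals of time — which
is what "stage I/II/III" means — and makes the segmentation nested in `k`
(boundaries at `k−1` are a subset of those at `k`; tested).  A free
complete-linkage ordering is still available for heatmap display.

The slow variety's developmental lag is estimated per time point as
`lag(t) = t − argmax_s PCC(fast_s, slow_t)` over the fast variety's grid
(ties to the smaller `s`).  A match at an end of the fast grid is marked
censored (the true match may lie off the observable range); the summary
`median_lag` is the median over uncensored time points.  Because the
estimator is grid-constrained, its resolution is limited by the local grid
spacing: 3 h over 0–12 HAI but 12 h over 12–48 HAI, so a planted 6 h lag —
exactly half the coarse spacing — is recovered to within ±6 h, while 0 and
12 h lags resolve exactly where trajectories still change.  After
germination completes the metabolome saturates and neighbouring profiles
become nearly collinear; lags read from that region are intrinsically
uninformative, which the censoring rule partly, but not fully, absorbs.

## Trajectory patterns

Candidate time courses (per variety by default; a pooled 16-point basis is a
switch) are standardized to z-scores with the sample SD; constant profiles
become all-zero and are labelled flat.  Classification: Spearman ρ of the z
profile against time calls accumulation (ρ ≥ 0.6) or consumption
(ρ ≤ −0.6); otherwise an interior maximum whose height clears both endpoint
z-values by ≥ 1 z-unit is accumulation-then-consumption (symmetrically for
an interior minimum); otherwise flat.  Both thresholds are configurable.
One guard precedes the rank rule in the pipeline: a profile whose raw means
vary by less than 5% (CV of the 8 means) is labelled flat outright.  Rank
statistics are scale-free, so without this gate arbitrarily small replicate
noise on a truly constant trajectory would be read as a monotone trend about
10% of the time (the chance that |ρ| of 8 exchangeable ranks exceeds 0.6) —
no amount of noise reduction fixes that, only a raw-scale floor does.

## Module annotation

Two bundled fixtures list the members of the ornithine–asparagine–polyamine
module (15 members: ornithine, L-asparagine and Asn + 2hexoside, consumed;
twelve polyamine entities — putrescine, spermidine, agmatine and
derivatives — accumulated, with N-acetylspermine special:
accumulation-before-consumption) and the shikimate–aromatic–flavonoid module
(14 members: shikimic acid, tyrosine, phenylalanine, tryptamine,
N-benzoyltryptamine, N-feruloyltryptamine, kynurenine, and seven flavonoids,
all accumulated except cyanidin 3,5-di-O-hexoside).  Members whose printed
source names are not individually legible are stored as explicitly flagged
placeholder rows (`ambiguous=true`) rather than guessed identities, so the
fixture cardinalities (15 + 14 = 29, asserted at load) are honest.  Matching
is exact after normalization (NFKC, lowercase, unified dashes, spelled-out
Greek letters, stripped spacing); no fuzzy matching.  Direction-consistency
summaries count a member as consistent when every variety's observed pattern
equals the fixture's expected direction; `special` members and members
absent from the data are reported as unevaluated.

A second fixture records the per-compound-class breakdown of the reference
74-candidate set (16 amino acids and derivatives, 12 polyamines, 9 lipids,
7 flavonoids, 6 organic acids, 5 terpenes, 3 nucleotides and derivatives,
2 phytohormones, 2 sugars, 2 vitamins and derivatives, 10 others).

## Phenotype computations

Water absorption rate `A_r = (W_a − W_b)/W_b × 100` (% of dry weight;
unit-invariant).  Germination rates are stored as fractions in [0, 1] and
compared between varieties, or between treatment doses and a control series
(label `CK`), by two-sided equal-variance Student's t-tests on per-dish
replicate fractions with star coding at 0.05/0.01/0.001.  Any treatment
concentration grid is accepted and echoed as given; published grids for the
shikimic-acid assay differ between report sections (lowest level 0 vs
0.01 μg/L), so the package deliberately does not impose one.

## Synthetic study design (what the generator emulates)

Defaults, fixed once as the validation conditions:

| parameter | default | meaning |
|---|---|---|
| `n_metabolites` | 400 | matrix width, near the ~380 of a targeted panel |
| `n_associated` | 60 | planted germination-associated metabolites |
| `positive_fraction` | 0.6 | fraction of associated metabolites accumulating |
| `timepoints` | 0,3,6,9,12,24,36,48 HAI | study sampling grid |
| `n_replicates` | 3 | biological replicates per variety × time point |
| `lag_hours` | 9 | slow-variety shift, centre of the reported 6–12 h range |
| `noise_cv` | 0.15 | multiplicative log-normal replicate CV, typical LC–MS |
| `effect_size_range` | (3, 6) | trajectory amplitude of associated metabolites |
| `baseline_floor` | 0.2 | relative floor of associated trajectories (≈15–30× dynamic range) |
| `germination_midpoint`, `germination_steepness` | 12 HAI, 0.3 /h | logistic germination curve |

Germination is logistic in time, shifted by `lag_hours` for the slow
variety; the phenotype table adds binomial 50-seed dish sampling (exactly
the noiseless curve when `noise_cv = 0`) and a triphasic water-uptake curve.
Associated metabolites track (or anti-track) the germination curve through a
linear link, so at zero noise their 6–48 HAI means correlate with
germination at exactly r = ±1; non-associated metabolites follow archetypes
(flat, shallow monotone ramps, interior Gaussian peaks).  All slow-variety
mean trajectories are the fast trajectories time-shifted by the lag (clipped
at the grid ends).  Replicate noise is `mean × exp(N(−σ²/2, σ²))` with
`σ² = ln(1 + CV²)`, so the expected replicate CV equals `noise_cv` exactly;
additive Gaussian noise is an option.  Outlier replicates are produced by
permuting a sample's metabolite vector, which preserves its marginal
distribution while destroying its correlation with siblings.  A plateau mode
(`plateau_boundaries=(12, 36)`) replaces trajectories with piecewise-constant
regime levels (log-normal, σ = 0.8 between regimes) to plant ground-truth
stage boundaries.  One seeded NumPy generator drives everything; identical
config + seed reproduces the dataset bit for bit.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: chromatographic drift and batch effects,
missing-not-at-random censoring at the detection limit, correlated metabolite
families (covariance here is driven by the shared germination curve plus
independent noise), heteroscedastic noise beyond the constant-CV model, and
biological replicate structure beyond exchangeability.

## Oracle and validation choices

- BH adjustment (statsmodels `fdr_bh`) is cross-checked against an
  independent textbook step-up implementation on random p-vectors.
- The analytic correlation p-value is cross-checked against scipy's
  `pearsonr` and against a 10,000-permutation null in 200 seeded cases.  The
  permutation check runs on series of 30 exchangeable points: with only six
  values the exact permutation null has 6! = 720 atoms and differs from any
  continuous approximation by far more than Monte-Carlo error, so six-point
  behaviour is pinned instead by the two closed-form worked examples.
- Recovery suites run 20 seeded replicates at 10% noise for stage boundaries
  (exact recovery required) and lag (median within 6 h, i.e. half the coarse
  grid spacing); screening sensitivity is checked at the default design
  (≥ 0.85) and for monotone improvement toward 1 as noise → 0.  These sizes
  keep the whole suite under a minute on one CPU while holding Monte-Carlo
  fluctuation well inside the asserted margins.

## Numerical choices and degenerate inputs

- Sample SDs use the n−1 denominator everywhere (CV, z-scores, t-tests).
- Constant series: correlation undefined → the metabolite is excluded from
  COR with a logged reason; a constant profile z-scores to zeros and is flat.
- `|r| = 1` returns `p = 0` with a degenerate flag.
- Segmentation ties break toward the earlier boundary (strict `>` with a
  1e-12 guard); lag ties take the smaller fast time point.
- Delimiters auto-detect between comma and tab; floats are parsed with
  pandas' round-trip precision so write→read is value-exact.
- Intensities are stored as given; no log transform at I/O.

## Known limitations

- The lag estimator is grid-constrained by design; sub-grid lags are only
  resolvable to the local grid spacing (see above).
- The per-variety union rule for COR/CV reflects one defensible reading of
  multi-genotype screening; the intersection rule is provided but changes
  candidate counts substantially.
- Module fixtures contain placeholder rows for members that cannot be
  enumerated from printed sources; direction-consistency summaries treat
  them like any other member when their names match, but they will simply
  never match real data.
- With three replicates the DAM t-test has low power at fold changes near
  the threshold; the BH gate makes borderline calls conservative.
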