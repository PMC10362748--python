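# Methods

## Design model

A study is a stage × truss grid of biological samples, optionally with
pooled-QC and extraction-blank samples. Stages are ordinal with a
numeric age in days post-anthesis; trusses are replicate blocks whose
fruit experienced slightly different microenvironments. The grid may be
incomplete (the reference design has 25 of 27 cells); all statistics
tolerate missing cells and missing values, which are stored as NaN and
excluded pairwise — never imputed as zero.

## Coefficients of variation

Both CV strata use the sample standard deviation (n−1). The smallest
stratum has three trusses, where the population form would noticeably
understate dispersion, and n−1 is what the common spreadsheet/R
toolchains compute, which keeps outputs comparable with hand
calculations on the same data. A CV is undefined (NaN, never an
exception) when fewer than two values are present or the mean is not
strictly positive; undefined features are retained in output tables but
can never be selected as stable.

The between-truss CV is the *mean of the per-stage across-truss CVs*; a
stage contributes only if at least two trusses are present, and the
number of contributing stages is reported per feature. The between-stage
CV is the CV of the per-stage truss means. Selection uses strict
inequality against the thresholds ("below 25%"), configurable to ≤, with
per-block defaults of 25%/25% for metabolome and proteome and 40%/40%
for transcriptome, where biological dispersion is higher and a 25% cut
would return too few features to analyse.

Per-category CV profiles group features by a prefix of their
hierarchical BIN code (top level by default). All pairwise two-sample
Wilcoxon rank-sum tests are run per CV stratum on the member CV
distributions, Benjamini–Hochberg corrected across the pairs of that
stratum, and flagged at corrected p < 0.01. BH was chosen because the
rest of the pipeline already uses FDR control; categories below three
members are excluded with a log notice.

## Untargeted LC-MS preprocessing

Order: blank filter → QC-CV filter → weight normalization. Each step is
idempotent and optional.

* Blank filter: a feature is removed when its mean biological abundance
  is below `blank_ratio_min` (default 3) times its mean blank abundance.
  "Present in the blanks" is not a crisp notion for continuous
  intensities, so the ratio rule makes the decision explicit and
  configurable; a feature silent in every blank always passes, and the
  boundary (ratio exactly 3) retains the feature (the rule is a strict
  <). Blank columns are dropped from the output.
* QC-CV filter: features with CV > 50% across ≥3 pooled-QC injections
  are removed. CV is scale-invariant, so this commutes with any
  per-feature rescaling; undefined QC CVs retain the feature.
* Weight normalization divides each sample column by its extraction
  mass (mg). With equal masses this is a constant rescaling and leaves
  every CV unchanged.

## Satellite collapsing

The rule table covers positive-mode ESI: +1.00335 Th (¹³C isotope),
+21.98194/+37.95588/+17.02655 Th (Na/K/NH₄ adducts relative to [M+H]⁺)
and −18.01056/−46.00548 Th neutral losses (H₂O, HCOOH); it is
user-extensible via a TSV. An edge requires co-elution (|Δrt| ≤ 5 s),
profile correlation (Spearman ρ ≥ 0.9 on shared present samples —
Spearman because detector response is monotone but not linear) and a
rule match within ±0.01 Th. Clusters are connected components; the
representative is the highest-mean-intensity member never assigned an
isotope or fragment role, with a deterministic id tie-break, and the
full member/role/rule provenance is reported so the (historically
manual) curation can be audited. Doubly-charged isotope spacing
(0.5017 Th) flags peptide-like ions; both partners are excluded from
metabolite-level stable sets.

## Sparse PLS

The two-block sparse PLS maximises u′X′Yv with an L1 (soft-threshold)
constraint on u. Implementation choices:

* keepX = ⌈select_ratio·q/ncomp⌉ per component (ratio 10 by default),
  i.e. the total X budget of ten variables per response metabolite is
  split evenly across components; the union over components can be
  smaller than the budget when components overlap, which is why
  selection counts can fall just below 10·q.
* The soft-threshold level is the magnitude of the (keepX+1)-th largest
  entry of the updated weight vector, giving exactly keepX nonzeros
  (up to exact ties, which do not occur with continuous data).
* Initialization is the leading right singular vector of X′Y and the
  sign convention makes the largest-magnitude X weight positive, so
  fits are bit-stable across runs. Convergence is declared when the
  weight vector moves by < 1e-9 (sign-invariant norm); non-convergence
  after 500 iterations warns and keeps the last iterate.
* Deflation is regression mode: X and Y are both regressed on the
  X-score, making successive X-scores exactly orthogonal and treating Y
  as the response. The Y block is never sparsified — all stable
  metabolites stay in the model.
* The 0.6 grouping threshold is applied to *variable–score
  correlations* (correlation-circle coordinates, bounded [−1, 1]), not
  raw loading vectors, which are scale-dependent; both blocks are
  correlated against the X-scores so metabolites and omics features
  live on the same bounded plot. A variable qualifying on several
  components is assigned to its largest-|r| component; groups are keyed
  by (component, sign) and empty groups are dropped.
* ncomp defaults to 2 (the two-component score/loading plots standard
  in this analysis); the end-to-end recovery runs use ncomp equal to
  the number of planted factors (3), since with fewer components than
  factors the weakest factor is structurally unrecoverable.

The implementation is validated against an SVD oracle in the dense
limit and against the mixOmics R reference implementation (selection
identity, loadings to 1e-6) in the test suite.

## Correlation screens

Spearman ρ is computed on average-ranked data over pairwise-complete
samples (≥4 required), with the two-sided p-value from the t
approximation on n−2 df — at n = 25 the exact permutation distribution
is unnecessary, and this matches the mainstream implementations; a
brute-force rank-then-Pearson oracle and an exact small-n permutation
check guard it in the tests. The unfocused screen keeps pairs at
p < 10⁻⁴ *without* multiple-testing correction, an explicit analysis
choice (correction would act differently on blocks of very different
width); an optional BH column is available but off by default.
"Assigned" targets are those with a functional annotation; a metabolite
is reportable when ≥10 assigned targets pass, and the largest top-level
BIN is tallied only over bins with more than two assigned hits. The
pathway screen ranks a metabolite's pathway members by |ρ|, keeps the
top 10 per target type with boundary ties retained (the tie rule is
deliberate: dropping arbitrary tied members would make the listing
seed-dependent), and lists those at p < 10⁻³; both the ranked and the
filtered tables are emitted.

## Enrichment

One-tailed hypergeometric tails per direction (the PageMan convention —
over- and under-representation are coloured separately) rather than a
single two-sided Fisher test: p_over = P[X ≥ k], p_under = P[X ≤ k]
under H(N, K, n). Features without an annotation form an explicit
"unannotated" pseudo-category, which can itself be depleted or enriched
in a selection. BH runs across the categories of one BIN depth; depths
are tested independently with no hierarchical dependency correction.
Raw p and FDR q are always both emitted; the `correct` flag only
selects which drives the significance column. The display statistic is
a signed probit of the smaller tail (+Φ⁻¹(1−p_over) / −Φ⁻¹(1−p_under));
it affects colouring only.

## Synthetic data: what it emulates, and what it does not

Abundances are lognormal: exp(baseline + stage effect + truss effect +
factor amplitude × stage profile + ε). On the log scale, small effect
standard deviations translate directly into CVs
(CV ≈ 100·√(exp(σ²)−1) ≈ 100·σ), which makes the planted classes easy
to reason about:

* stable features: stage sd 0.08, truss sd 0.07, residual 7% — expected
  between-stage CV ≈ 10%, between-truss CV ≈ 11%, comfortably inside
  the selection thresholds;
* varying features: a modest i.i.d. per-stage effect (sd 0.1) plus a
  large per-sample dispersion (sd 1.2), giving between-stage CVs around
  75%. The dispersion is placed mostly at the sample level because with
  only nine stages a purely stage-level draw would routinely produce
  spurious |r| > 0.6 correlations with any smooth latent profile
  (effective df ≈ 8), contaminating covariation groups with features
  that covary with nothing;
* latent factors: three smooth, mutually orthogonalized stage profiles
  (early peak, mid peak, ramp-up — the canonical division, expansion
  and ripening phases). Factor amplitudes decrease across factors
  (1.15/0.95/0.8 on the omics side, 0.13/0.12/0.11 on the metabolite
  side) so the cross-covariance singular values stay separated;
  near-degenerate factor strengths would let the PLS components rotate
  arbitrarily inside the factor subspace. Per-factor group sizes
  (70/69/68 per block) sit just below keepX = ⌈10·22/3⌉ = 74, so the
  number of spuriously selectable variables per component is capped by
  the few free slots — chance |r| > 0.6 correlations are unavoidable at
  n = 25 (null rate ≈ 1.5·10⁻³ per feature), and the cap is what keeps
  group recovery robust rather than luck;
* factor metabolite amplitudes are kept low (≈0.13 log-sd) because the
  peaked profiles are right-skewed after exponentiation and realize
  natural-scale CVs noticeably above the naive lognormal formula; the
  chosen values keep factor metabolites safely below the 25% selection
  threshold while their profile correlations (≈0.8) clear the 0.6
  grouping gate;
* LC-MS satellites: parent intensity × role ratio (isotope 0.25, adduct
  0.4, fragment 0.3) × 2% lognormal jitter, with m/z offsets drawn
  within ±0.003 Th of the rule deltas and retention times within ±1 s
  of the parent; one doubly-charged peptide pair at 0.5017 Th spacing
  with stable-looking CVs (so that *failing* to flag it would corrupt
  the stable set); blank contaminants as abundant in blanks as in
  samples; a few features with deliberately unstable QC response; and
  an extraction-weight nuisance (18–22 mg) multiplied onto the columns,
  which weight normalization removes;
* categories: ten top-level BINs assigned uniformly, with one BIN per
  factor boosted 5× among that factor's members (planted enrichment);
  annotation rates 0.6 (proteins), 0.4 (transcripts), 0.8 (factor
  members), so "unannotated" depletion in covariation groups is part of
  the planted structure.

Desk-scale defaults (metabolome 300, proteome 1,000, transcriptome
3,000 features over 25 + 3 QC + 2 blank samples) keep the full pipeline
under a few seconds; a full-scale configuration (1,243/2,282/23,631
features, the sizes typical of such studies) is a configuration away. An infeasible configuration — stable-CV expectation
exceeding its budget given the noise level — is rejected before
generation.

What the generator does **not** emulate: real metabolite identities or
concentration scales, platform drift and batch effects, heteroscedastic
(intensity-dependent) noise, correlated truss effects across features,
or the strong global stage separation real metabolomes show (the
synthetic PCA spreads variance across many components, where real data
concentrate most of it on PC1/PC2). Passing the recovery tests
therefore demonstrates that the algorithms are correct and calibrated
under the assumed generative model, not that real data will be as
clean; on real matrices the manual-curation steps the rule engine
replaces (satellite merging, annotation) remain approximations.

## Numerical conventions

* Delimiters are auto-detected among tab/comma/semicolon; decimal
  points are mandatory.
* Representative and cluster ordering, BH ties, and PLS signs are all
  deterministically tie-broken, so identical inputs give byte-identical
  outputs; the only randomness in the package lives in the simulator
  and is fully seeded.
* Features with fewer than three present biological samples are
  droppable from analyses (the smallest stratum has three trusses).
* p-values are clipped away from 0 only for the probit display, never
  for inference.

## Known limitations

* The satellite graph is O(pairs) within an m/z window; fine at desk
  and full study scale, not engineered for ion-mobility-sized feature
  lists.
* The sPLS keepX schedule (even split across components) and the
  0.6 correlation threshold are conventions, not estimates; no
  cross-validation of ncomp is performed.
* Spearman p-values use the t approximation uniformly; for n < 10 an
  exact permutation test would be preferable (the tests quantify the
  gap at n = 7 as ≤ 0.02 absolute).
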