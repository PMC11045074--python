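# Methods

`kinlod` infers close kin among individually biopsied animals from diploid
microsatellite genotypes. It was built for feeding-ground biopsy surveys of
southern right whales — opportunistic sampling over many seasons, moderate
numbers of loci, visually estimated body lengths, maternally inherited
mtDNA haplotype labels — but nothing in the machinery is species-specific.

## Pairwise kinship model

For two individuals with single-locus genotypes `g1, g2`, the probability
under a kinship hypothesis K with Cotterman IBD coefficients
(κ0, κ1, κ2) is

    P(g1, g2 | K) = κ0·P(g1)P(g2) + κ1·P(g1)T(g2|g1) + κ2·P(g1)·1[g1=g2]

where `P` is the Hardy–Weinberg genotype probability (with the 2pq factor
for heterozygotes) and `T` the Mendelian parent–offspring transition (one
allele transmitted with probability 1/2, the other a population draw). The
hypothesis set is U = (1,0,0), PO = (0,1,0), FS = (1/4,1/2,1/4),
HS = (1/2,1/2,0) and SELF = (0,0,1). HS also covers grandparent–grandchild
and avuncular pairs: all second-degree relationships share this likelihood
and cannot be separated from pairwise genotypes. Loci are treated as
unlinked and in linkage equilibrium; inbreeding (9-state identity
coefficients) and mutation in transmission are out of scope.

### Genotyping error

Observed genotypes pass through a constant, independent per-allele error
channel. Default `epsilon = 0.0077` per allele, the rate used for the
congeneric North Pacific population's markers. Two replacement modes are
available because the literature rarely states one:

* `freq_draw` (default): with probability ε the observed allele is a fresh
  draw from the population frequencies (self-replacement allowed);
* `uniform_other`: with probability ε a uniform draw over the other k−1
  alleles.

The channel is applied per allele and summed over all true-genotype pairs,
so every observed pair has strictly positive probability when ε > 0. That
keeps the LOD score

    LOD_K(i, j) = ln P(G_i, G_j | K) − ln P(G_i, G_j | U)

finite everywhere; without it a single typing error at one locus would
drive LOD_PO to −∞ for a true parent–offspring pair. LODs are summed over
the loci typed in both individuals (`n_loci_used` is reported); natural
logarithms throughout.

Per-locus tables of P(observed pair | K) are precomputed and cached in a
`KinshipModelContext` (the table is `E·M·Eᵀ` for the genotype-level error
matrix `E` and true-pair matrix `M`, explicitly symmetrised so LOD symmetry
is exact in floating point). Scoring a pair is then one table lookup per
locus; all 14,535 pairs of 171 individuals score in well under a second.

### Maximum-likelihood classification

Each pair is assigned the category (PO, FS, HS or U) with the highest LOD;
since the U denominator is common, this is the highest pair likelihood.
Ties break toward the *less* related category (U ≻ HS ≻ FS ≻ PO),
conservative against false kin. SELF is excluded from this set — it is
used only during duplicate detection.

## Allele frequencies and QC

Allele frequencies are plain observed counts over typed alleles. They are
estimated twice: once on all samples to drive duplicate detection, then
re-estimated on the unique individuals for all downstream scoring, so
duplicate biopsies do not double-count alleles.

Hardy–Weinberg agreement is checked per locus by chi-square goodness of
fit, pooling genotype classes with expected count < 5 into one class;
df = (#classes − #alleles), clipped at 1. Monomorphic loci return a
defined "not testable" result.

## Duplicate and resample detection

Two biopsies of one individual are detected with the same LOD machinery:
a pair is merged when its SELF-vs-U LOD exceeds a threshold *and* SELF is
the maximum-likelihood category among {U, HS, FS, PO, SELF}. The joint
condition matters: a parent–offspring pair can clear a permissive LOD
threshold, but its PO likelihood always dominates SELF, so the ML
condition protects true kin from being merged away.

The default threshold targets fewer than 0.01 expected false merges in a
dataset of the observed size. The implied per-pair rate (~10⁻⁶ at study
scale) is far below plain Monte-Carlo resolution, so the threshold is set
by a normal-tail extrapolation of the simulated unrelated-pair SELF-LOD
distribution (mean + z·sd, z = Φ⁻¹(1 − 0.01/n_pairs)), clamped below the
0.1% quantile of the simulated SELF distribution. With 14 informative loci
the two distributions sit tens of LOD units apart (unrelated pairs around
−70, re-typed duplicates above +30 even with a typing error), so the
precise threshold is uncritical. Merged groups sharing date and position
are tagged `same_place_time_duplicate`, others `resample`; the earliest
biopsy is retained (ties by sample id).

## Cut-off calibration

LOD distributions per kinship category are simulated from the fitted
context: per locus, draw the IBD state from κ, build true genotypes under
HWE + Mendelian transmission, apply the error channel, score with the same
cached tables. The study-scale default is 10⁶ pairs per category; tests
and the acceptance script use 2×10⁴–10⁵, which resolves the rates that
matter at the cutoff (FP ≈ 2×10⁻⁴, FN ≈ 0.2) with adequate precision.
Under unrelatedness the LOD_PO distribution is multimodal: each mode
corresponds to a count of loci Mendelian-incompatible with PO, every such
locus contributing a discrete ≈ log ε penalty.

For a cutoff c and target category,

* FP rate(c): fraction of simulated U pairs with scored LOD > c *and*
  ML category equal to the target;
* FN rate(c): fraction of simulated target-category pairs failing that
  joint criterion.

Expected FP counts multiply the rate by the total number of pairs compared
(related pairs are a negligible fraction). Rates with zero exceedances are
reported with a "< 1/n" resolution bound, never extrapolated. The
bias-corrected kin count is

    corrected = observed − expected FP + expected FN,

where the FN expectation scales with the unknown *true* count, resolved by
fixed-point iteration `N = observed − FP + fn_rate·N` (tolerance 10⁻⁶;
equivalently (observed − FP)/(1 − fn_rate)).

Two finite-sample caveats, both measured on planted-truth simulations and
both properties of the plug-in-frequency method rather than of this
implementation:

* the simulated FN rate tracks the empirical detection rate closely
  (0.829 vs 0.820 over 600 planted PO pairs);
* the simulated expected FP slightly overestimates realized false
  positives (2.80 vs 2.18 per 14,535 pairs) because real pairs arise from
  the true allele frequencies while scoring and calibration both use
  frequencies estimated from the sample itself — self-consistent for the
  simulation, mildly misspecified for the data. The net bias on a true
  count of 10 is under one pair.

## Dyads, annotation, triads, elapsed time

Dyads are pairs with scored LOD (by default LOD_PO) above the cutoff,
default 6, sorted by descending LOD. FS-classified dyads are kept but
flagged low-confidence: at 14 loci the FS likelihood overlaps both PO and
HS heavily, so such pairs are plausibly PO or HS.

Maternal-consistency annotation uses the maternally inherited haplotype
and genetic sex: shared known haplotype with sexes {M,F} → MS
(mother–son compatible), {F,F} → MD (mother–daughter compatible),
{M,M} → no label; differing haplotypes → none; any unknown → n/a. The
label never designates which member is the parent — with both body
lengths known, the larger individual is flagged *presumed* mother as a
consistency note only. A female triad labelled MD/MD is equally consistent
with a mother and two daughters or a grandmother–mother–grandchild chain;
age data would be needed to separate them, so both readings stand.

Triads are connected components (≥ 3 members) of the dyad graph; shared
individuals are those with degree > 1. Elapsed time between the two
samplings is the calendar-day difference divided by 365.25 and floored, so
same-season pairs report 0 years.

## Spatial association

Geography enters as Δ longitude — the minimal angular difference, wrapped
across the antimeridian to [0°, 180°] (sampling spans the 180° meridian) —
rather than great-circle distance, because the question is longitudinal
spread along a circumpolar feeding ground.

* **Rank test.** Two-sample Wilcoxon (Mann–Whitney) of Δ longitude between
  ML-classified PO and U pairs, two-sided; exact enumeration when both
  groups have ≤ 10 pairs (tie handling follows the exact null without tie
  correction), otherwise the normal approximation with tie correction.
  HS-classified pairs are excluded; no LOD cutoff is applied to the PO
  group, trading some false positives for sample size. Field-observed
  mother–calf pairs are excluded (their proximity is known by
  construction). Pairs sharing an individual are not independent;
  simulation of the null at reduced scale shows the type-I error stays
  near nominal despite this.
* **Tail quantile regression.** LOD_HS regressed on Δ longitude and
  SameDayPos (same calendar day, same survey vessel) at upper quantiles τ,
  minimising the pinball loss Σ ρ_τ(y − Xb). The general fit uses the
  iteratively reweighted least-squares solver in statsmodels `QuantReg`;
  degenerate designs drop constant columns and an intercept-only fit uses
  the closed-form order-statistic minimiser (which satisfies the residual
  sign-balance identity exactly; the full fit satisfies it to within
  p/n). 95% bands are pair-level percentile bootstrap, seeded; residual
  dependence between pairs makes these bands approximate. Close kin live
  in the far right tail of the LOD_HS distribution, so a kin excess among
  proximate pairs appears as a SameDayPos effect concentrated near
  τ ≈ 0.95, not as a mean shift.
* **ECDF comparison.** Empirical CDFs of LOD_HS split by SameDayPos, with
  a reference line at the median of the simulated HS distribution — the
  region where half-sibling-type relatives would surface.

Sector defaults differ on purpose: the restricted rank test uses 85°–135°E,
the quantile regression 80°–135°E; both configurable.

## Synthetic data

The real genotypes are available only on request, so the generator is a
first-class module. It emulates: 14 loci with 2–15 alleles
(Dirichlet-sampled frequencies, floored at 10⁻⁶), HWE founders, Mendelian
transmission, maternal haplotype inheritance from a pool of 8, per-allele
error 0.0077, near-equal sex ratio, sampling seasons December–March
1993–2019 concentrated 85°–135°E south of 60°S with ~8% lower-latitude
events, shared date/vessel/position for mother–calf events, and duplicate
(same place and time) plus resample (different season) biopsies. Body
lengths are simple normals (adults 13.5 ± 1.2 m, calves 10.0 ± 0.8 m) —
enough to exercise the presumed-mother flag, with no growth model. It does
*not* emulate: movement or site fidelity, age structure, null alleles or
allelic stutter, linkage, or realistic spatial clustering beyond the
sector blob — so passing tests demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to these
real-data features.

`study_fixture(seed)` pins a study-shaped dataset: 183 samples of 171
individuals (4 duplicates, 8 resamples), ten independent PO pairs (four
field-flagged mother–calf), one mother with two daughters (a triad whose
daughters are half sisters), three HS pairs and one FS pair.
`planted_kin_sample` gives unrelated individuals plus a chosen number of
independent PO pairs for recovery experiments. `planted_tail_shift_pairs`
builds the quantile-regression testbed: every pair draws a latent uniform
u mapped through a Normal(−8, 3) base quantile function, and SameDayPos
pairs (12%) additionally gain 1.8·w(u) with w ramping 0→1 over
u ∈ [0.91, 0.94]; by the inverse-CDF argument the between-group τ-quantile
difference is exactly 0 for τ ≤ 0.91 and exactly +1.8 for τ ≥ 0.94. Its
default 10⁴ pairs matches the scale of a ~1.2×10⁴-pair sector analysis;
at a few thousand pairs the bootstrap distribution of the tail coefficient
becomes bimodal and the experiment loses power.

## Numerical and design notes

* Genotypes are canonical sorted pairs; equality is representation-
  independent. Longitudes live in (−180°, 180°]; dates are ISO-8601.
* Error-channel and probability tables are validated at build time (rows
  and totals sum to 1 within 10⁻¹²); pair-probability tables are checked
  against an independent generative enumeration to 10⁻¹² in the tests.
* The likelihood-ratio identity E_U[exp(LOD_PO)] = 1 is verified by
  simulation on a 3-locus low-information context. At 14 informative loci
  the estimator's second moment is ~4×10⁶ — the expectation is carried by
  unrelated pairs that look like PO at rates below plain-Monte-Carlo
  resolution — so a sample mean with a 3-SE bracket is meaningless there;
  on the small context the second moment is 3.2 and the bracket is sound.
* Monte-Carlo problem sizes used by the test suite and acceptance script:
  2×10⁴ calibration pairs per category per run (10⁶ remains the study-scale
  default in `PipelineConfig`), 10⁵ pairs for the identity check, 20
  planted-truth recovery runs, 150 bootstrap resamples per τ. These sizes
  resolve the quantities they estimate at the tolerances asserted.
* All randomness flows from explicit integer seeds; identical inputs,
  config and seed reproduce outputs byte-for-byte.

## Known limitations

* Second-degree categories are reported as HS but may be GP or AV; FS
  calls are weak evidence at this marker power.
* The kin-count correction inherits the plug-in-frequency bias described
  above (small at study scale, grows as loci become fewer or kin rarer).
* Tail FP rates below Monte-Carlo resolution are bounded, not estimated
  (no importance sampling).
* The Wilcoxon and bootstrap procedures treat pairs as exchangeable units;
  dependence from shared individuals is quantified only empirically.
* Abundance estimation from kin counts (close-kin mark-recapture proper)
  is deliberately out of scope.
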