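# Methods

`ventree` re-implements, as a tested pipeline over synthetic data, a
molecular-fingerprinting workflow for hydrothermal-vent organic matter:
GC-EI-MS runs are deconvolved into purified compound spectra, aligned and
co-annotated across samples, organized into a molecular relatedness tree
cut into alteration stages, complemented by FT-MS molecular-formula class
profiling and Hg isotope δ/Δ systematics. This note records the models,
the committed numerical choices, and what the synthetic data do and do
not establish.

## Synthetic data model

The generator is first-class code: it defines the study conditions every
downstream claim is measured under.

**Compound library.** Nine compound families (alkanes, alkenes,
halogenated compounds, biomarkers, aromatics, O-, S-, N-compounds,
other), each with a stylized 70 eV fragmentation template: alkanes the
43/57/71/85 Δ14 ladder with a weak molecular ion, alkenes the 41/55/69
series, aromatics a dominant molecular ion with M−1/M−26 satellites,
biomarkers sterane-type diagnostic ions (217/231/213/191), heteroatom
classes shifted series (31+14k for O, 30+14k for N), halogenated
compounds an M/M+2 chlorine doublet. Templates are self-consistent, not
compound-accurate; every test depends only on recovery of what was
generated. Same-class compounds are placed ≥ 0.5 min apart: two
homologues with near-identical fingerprints closer than a peak width are
physically a single unresolvable signal, so a generator that produced
them would be positing an impossible measurement, not a harder test.

**Runs.** Compounds elute as exponentially modified Gaussians
(FWHM 0.1 min, τ = 0.2 σ) on a fixed 0.01 min scan grid spanning
1–87 min (the 40→290 °C at 4 °C/min program). Fragment m/z values carry
a fixed sub-Da offset from nominal so integer binning is exercised. A
broad Gaussian UCM hump (amplitude 2×10⁵ by default) rides on the
alkyl-fragment traces; white Gaussian noise (σ = 2×10⁴) is added to
every occupied trace and clipped at zero — clipping plus many compounds
sharing nominal bins produces the positive, bin-dependent baseline floor
that the deconvolution stage must remove, as in real data. Noise is not
added to never-occupied bins; an all-bins floor would multiply memory
without exercising anything (peak spotting already faces noisy occupied
traces).

**Panels.** Default geometry mirrors the study: 12 samples cycling
3 vent fields × 2 activity states; exactly round(shared_fraction · n)
compounds appear in every run, the rest in strict subsets drawn with
activity-dependent class weights (active runs hydrocarbon/aromatic-rich,
inactive runs NSO-rich). Chimeric co-elution is decided once per panel —
co-elution is a property of the compounds, not of one injection — by
relocating 20 % of compounds 0.02–0.05 min from a partner of a
*different* family (partial spectral overlap; a same-family pair shares
essentially every fragment and is unidentifiable in principle). Each run
then adds a systematic retention shift (σ = 0.008 min) plus sub-scan
per-compound wobble, exercising the 0.075 min alignment tolerance
without destroying pair geometry.

**FT-MS peak lists** draw valid formulas per chemical family
(CHO/CHON/CHOCl/CHONCl) from a realistic dissolved-organic-matter space
(C 8–44, H/C 0.6–2.2, O/C ≤ 0.9, N ≤ 3, Cl ≤ 2, integral DBE ≥ 0),
compute the [M−H]⁻ monoisotopic mass, and jitter it by Gaussian ppm
error. **Hg tables** encode δ/Δ truth as xxxHg/198Hg ratios on the
nominal IUPAC abundance scale with exact bracketing-standard rows, so
the δ computation inverts them exactly at zero noise.

**What passing does not show.** The generator has no retention-index
drift curvature, no detector saturation, no isotopologue peaks, no
electronic spike artifacts, and templates are far better separated in
spectral space than real isomer families. Recovery rates here bound the
method's behavior under its own assumptions; they do not certify
performance on real vent extracts.

## Deconvolution

Centroids are binned to nominal mass (0.5 rounds up), smoothed with a
triangular (linear-weighted) moving average of level 3 (window 7,
truncated-renormalized edges). Peak spotting keeps local maxima of the
smoothed trace with height *and prominence* ≥ the minimum peak height
(default 3.5×10⁵ detector units, inside the 3–4×10⁵ band appropriate to
the synthetic response scale); prominence is what makes "significant
above the baseline noise" literal on traces whose stacked-noise floor
alone exceeds the height threshold. Edges walk down each flank to the
first local minimum, capped at ±40 scans because noise-free EMG tails
otherwise decay monotonically for minutes. Candidate model peaks are
scored quality = height × ideal-slope × sharpness with the committed
definitions (ideal slope = 1 − wrong-direction step fraction per flank,
averaged; sharpness = flank rise per step / √height); co-apexing
candidates within ±1 scan form one cluster, whose head is the
highest-quality peak (ties: earlier retention time).

Fragment traces are gathered a tier below the model threshold
(0.1 × min peak height) and attributed to a model when their apex lies
within sigma_window (0.5) × the model half-width-at-half-maximum, or
when their peak span covers the model apex (the merged-peak case of a
chimeric pair). Within each co-elution window, traces are baseline
corrected by their 10th percentile over the window (removing the UCM
hump and stacked noise floors; the correction is scale-invariant so
relative intensities are unaffected), initial elution profiles are the
pointwise median of normalized cluster-member traces (voting out members
contaminated by a co-eluter), clipped to the model span, and the
bilinear system is refined by alternating nonnegative least squares
(MCR-ALS: NNLS over fragments, then NNLS over scans) until the relative
residual reaches 10⁻⁹ or stalls. On noise-free input with identifiable
components this converges to the exact factorization, which is why the
reconstruction residual invariant (< 10⁻⁶ relative) is testable at all.
Reconstructed fragment amplitudes are kept when ≥ the EI cutoff (10.0
detector units, the committed unit reading of an otherwise unitless
setting) *and* ≥ 3× the robust (MAD) residual noise of their own trace;
a spectrum is emitted only if its baseline-corrected base peak clears
the minimum peak height.

## Similarity, annotation, alignment

Spectral similarity is a √intensity-weighted cosine with greedy
nearest-m/z matching (tolerance 0.5 Da), computed over the union of
matched and unmatched peaks. Library matching combines forward cosine,
a reverse cosine over the matched pairs only (1.0 when the query is a
proportional fragment subset of the reference), and the fraction of
significant (≥ 10 % relative) reference peaks present in the query;
total = their mean, gated at 0.70 for an identification.

Alignment considers cross-sample spectrum pairs with |Δrt| ≤ 0.075 min
and cosine ≥ 0.70, scored 0.5·(1 − |Δrt|/tol) + 0.5·cosine, merged
best-score-first under the constraint of one hit per sample per feature.
Two pragmatic cleanups, both standard in feature alignment, keep ghost
duplicates (one compound reported twice a couple of scans apart) from
splitting features: near-identical spectra within 0.03 min inside one
run are collapsed to the strongest, and after merging, feature groups
within 0.03 min whose strongest members match at cosine ≥ 0.85 are
consolidated keeping the stronger hit per sample. A feature's
representative is its highest-identification-score hit (ties: smallest
sample id); without a library the score is the mean cosine to the
feature's other hits. Co-annotation keeps features with hits in every
sample.

The 20/50/70 % triple check is computed on a single alignment at the
loosest threshold: a feature qualifies at threshold t when its hits stay
connected across all samples using only pairs with cosine ≥ t. This
makes the nesting S(70 %) ⊆ S(50 %) ⊆ S(20 %) a theorem rather than a
hope — independent greedy re-alignments per threshold cannot guarantee
it — so a nesting violation genuinely signals a bug.

## Relatedness tree

All unordered pairs of representative spectra are scored with the
composite similarity (654 features → 213,531 evaluations); distance is
d = 1 − s (bounded, unlike −log s). The tree is UPGMA — the
fingerprint "phylogeny" is average-linkage clustering, since no
substitution model exists for EI spectra — implemented with
Lance-Williams updates, merge height d/2, ties broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest member id), which makes the tree input-order invariant.
Neighbour joining (via scikit-bio) is offered as an alternative.
The k-stage cut removes the k−1 highest merges; stages are numbered in
circular leaf order starting from the clade richest in alkanes,
anchoring "stage 1" to the saturated-hydrocarbon end of the alteration
gradient. Newick export writes parent-minus-child heights; parsing goes
through scikit-bio.

## FT-MS formula assignment

Formula enumeration is exhaustive over the bounded CHNOCl grid
(defaults C 1–130, H 1–200, N ≤ 5, O ≤ 30, Cl ≤ 3, window |err| ≤
ppm_tol, DBE 0–40 integral, H/C 0.2–3.1, O/C 0–1.2), vectorized over a
cached (C,N,O,Cl) grid with the hydrogen count solved from the residual
mass (hydrogen spacing ≫ any ppm window). Candidates are listed by
|error|; assignment, however, ranks by a penalized likelihood
err²/(2σ²) + λ·(N+Cl) with σ the instrument mass accuracy (0.5 ppm) and
λ = 0.5. Plain smallest-error ranking fails in two measurable ways: a
2σ-wide window already excludes ~5 % of true formulas, and the CHNOCl
space contains frequent sub-mDa doublets (e.g. ΔC+13 ΔH−8 ΔN+2 ΔO−11 ≈
0.47 mDa) that flip a coin at ppm accuracy. The heteroatom-parsimony
prior is standard DOM-assignment practice; λ was calibrated on
simulation to minimize class-proportion bias across the activity
scenarios while keeping true-formula top-rank recovery ≥ 95 % below
m/z 500. `dom_assignment_config()` packages the analysis settings
(window = 3σ; N ≤ 3, Cl ≤ 2 — the element space vent DOM occupies);
the wider spec-style bounds remain the constructor defaults.

Class profiles count formulas (not intensities) into CHO / CHON /
CHOCl / CHONCl; the N-bearing proportion is (CHON + CHONCl)/total, with
per-class oxygen-atom histograms. Scenario comparison reports pairwise
differences with Wald two-proportion z-intervals and a monotone-rise
flag, mirroring the 29.9 % → 47.9 % → 51.3 % enrichment pattern across
vent activity states.

## Hg isotopes

δxxx = (Rsample/Rstd − 1)·1000 ‰ against the arithmetic mean of the
bracketing standards (the bracketing combination rule is a committed
choice); Δxxx = δxxx − β·δ202 with β = 0.252, 0.5024, 0.752 for
199/200/201. Replicate summaries report mean and 2SD per quantity and
flag missing secondary-standard slots against the every-7-samples QC
schedule. The zero-noise simulate→invert round trip is exact to
10⁻¹² ‰, and Δ is linear in its inputs.

## Problem sizes

The test suite and acceptance script run the study geometries directly:
the 12-sample / 200-compound / 87-min panel for alignment and
co-annotation (about a minute of compute), the 50-compound chimeric run
for deconvolution, 654 features for the pair-count bound, 500-formula
peak lists plus 2200/4100/3000-formula activity scenarios for FT-MS.
The numbered `analysis/` scripts use a 6-sample, 90-compound, 40-min
demonstration panel so the full narrative reruns in about a minute;
they regenerate everything deterministically from seeds rather than
shipping intermediates.

## Known limitations

Same-family compounds co-eluting within a peak width are returned as
one merged spectrum — with near-identical fingerprints the mixture is
rank-deficient and no decomposition can split it. The greedy best-first
alignment has no global objective; pathological panels could split a
compound across features, which the consolidation pass mitigates but
does not preclude. Formula assignment models no isotopologue evidence,
so its doublet arbitration rests entirely on mass error and the
parsimony prior. The stage cut assumes the class gradient is the
dominant structure in the similarity matrix; with weak class separation
the alkane-richest anchoring still defines stage 1 but stages lose
geochemical meaning.
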