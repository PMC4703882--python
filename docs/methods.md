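# Methods

This note records the models, conventions and numerical choices behind
`fascreen`, and what the synthetic generators do and do not emulate.

## Family variant model

Variants are biallelic after loading; multiallelic VCF records are split at
read time, and for the record carrying alternate allele *k* any other called
alternate reads as non-carrier of *k*. Coordinates are 1-based VCF
convention; the reference build is a pass-through label. Allele calls take
three states (REF, ALT, NOCALL) per diploid slot. A genotype is HIGH quality
iff its record passes FILTER and its GQ is ≥ 20 (GQ absent ⇒ HIGH when FILTER
passes); this stands in for the high-confidence variant flags of platforms
whose native formats VCF does not carry. No left-normalization is performed —
inputs are assumed normalized, and a violation surfaces only as a
duplicate-key or conflicting-reference error in the union step.

Allele presence per genome is PRESENT iff ≥ 1 slot carries the alternate,
ABSENT iff both slots are called reference, NOCALL otherwise; these three
outcomes partition all nine call-pair combinations.

### Kinship

Pairwise kinship uses the robust concordance estimator
φ̂ = (N_hethet − 2·N_opphom) / (N_het,a + N_het,b) over fully-called biallelic
SNVs with a known panel frequency (≥ 1,000 required). The classic
frequency-product moment estimator Σ(g_a−2p)(g_b−2p) / 4Σp(1−p) is
unsuitable here: a union of family variants contains no site carried by
nobody, and that carrier ascertainment inflates the product-moment φ for
transmitting pairs to ≈ 0.5. The concordance ratio is exactly invariant to
it, because conditioning on "≥ 1 parental carrier" removes only
double-hom-ref configurations, which contribute to neither numerator nor
denominator. Degree bins use the standard boundaries φ ≥ 2^−(d+3/2); below
2^−10.5 a pair is reported "≥ 9th-degree/unrelated".

## Prioritization funnel

Stage order is fixed: quality → frequency → proband carrier → consequence →
inheritance model → predictor consensus. Each stage keeps a subset of its
input, so stage counts are non-increasing and each filter is idempotent; the
first three stages evaluate independent per-variant predicates and therefore
commute. The frequency cut is inclusive (MAF ≤ 0.01 passes) and a variant
absent from every panel passes — a novel causal variant must survive this
stage. Predictor scores arriving as raw values are binarized at SIFT ≤ 0.05,
PolyPhen ≥ 0.446, MutationTaster class A/D, CADD ≥ 20 (all overridable; the
consensus rule itself — ≥ k of m DAMAGING with missing counting as
non-positive — is separate from the binarization). The consensus filter runs
after the inheritance model; for a compound-het pair both variants must pass.

## Inheritance models

No-call handling is deliberately asymmetric. The compound-het screen is
permissive — an uncalled allele is compatible with any required state, and
the index qualifies as heterozygous with exactly one ALT slot and the partner
slot REF or NOCALL (one ALT slot is positive evidence; two would be
homozygous). The de novo screen is strict — a single uncalled allele in a
parent or the sibling disqualifies the site, because a de novo claim rests on
positive evidence of absence everywhere else; the sibling-absence requirement
is configurable. The recessive screen demands a fully called homozygous
index even though the upstream carrier filter retained NOCALL-index variants:
model assignment needs called genotypes.

For a compound-het pair the parental assignment is a two-case constraint
problem: (vA paternal, vB maternal) is consistent when the father is
PRESENT-or-NOCALL for vA and ABSENT-or-NOCALL for vB and the mother the
converse. A variant het in both parents can participate whenever *some*
consistent assignment exists. If both assignments are consistent the one
with more called PRESENT parental evidence is reported, ties defaulting to
first-variant-paternal, so reported origins are always {PATERNAL, MATERNAL}.

Candidate genes are ranked by counting three criteria — relevant function,
interaction with known FA proteins, and an external FA-likeness score at or
above 6.224 (the printed score of list position 150 in the reference ranking;
configurable) — then by score, then gene symbol; unscored genes sink to the
bottom. The criteria are combined by count-then-score because the source
analysis applies them narratively, without weights.

## Revertant clones

The decision table is total and mutually exclusive over all 4×3×3×4 state
combinations. Both flanking SNPs must agree before a mechanism is called:
homozygosity of both ⇒ LOH, heterozygosity of both (with wild-type-only
RAD51) ⇒ back mutation, anything mixed or uncalled ⇒ AMBIGUOUS. A
mutant-only clone with heterozygous flanking SNPs would be a forward mutation
of the wild-type base — a class outside this scheme — and is AMBIGUOUS.
The reversion percentage is n_wt_only/n_clones rounded half-up to an integer
(7/58 → 12%). The LOH direction test, P(X ≥ n_wt | n, ½), is an added
formalization of the qualitative observation that no mutant-only clone
appears, and is labelled as such in reports.

## Filament morphometry

Constants: B-form rise 0.34 nm/bp; coated rise 0.51 nm/bp (1.5× extension);
discontinuity threshold 1.0 nm; reference substrate 3,901 bp.

Tracing replaces manual contour tracing with an automated ridge trace:

1. Gaussian pre-smooth (σ = 1 px) to suppress single-pixel noise.
2. Threshold at background median + 0.35 nm. The threshold sits *below* the
   bare-duplex apex (~0.5 nm, attenuated to ~0.45 nm by the pre-smoothing) so
   that a trace follows naked DNA through protein-free gaps instead of
   fragmenting; a 2-px binary closing bridges residual dropouts.
3. Skeletonize; per connected component take the longest geodesic path
   through the 8-connected skeleton graph (double-sweep Dijkstra), which
   prunes spurious side branches.
4. Savitzky–Golay smooth the pixel path (window 9, order 2) to undo
   stair-stepping, then snap each point to the ridge crest by a sub-pixel
   parabolic fit of the perpendicular height profile — smoothing removes
   real curvature along with grid noise, and crest snapping restores it.
5. End correction: a finite probe extends the imaged ridge past the filament
   end by about the ridge's own half-width (tip dilation acts like a rolling
   maximum), so each end is placed at the along-axis half-plateau crossing
   pulled back by the perpendicular half-width-at-half-max measured on the
   same ridge. Without this step short filaments read several percent long
   or short depending on threshold.
6. Resample at 1-px arclength spacing; heights along the trace come from the
   raw (unsmoothed) map.

Contour length is the summed Euclidean step length × pixel size. On
noiseless fully coated renders of 500–4,000 bp the measured extension ratio
stays within 2% of 1.5. A discontinuity is a maximal run of ≥ 2 consecutive
trace samples below 1 nm; single-sample dips are noise by definition, and
runs touching a trace end are end taper, not gaps. Group summaries report
mean ± s.e.m. (sample sd/√n; absent for n = 1).

## Biochemical quantifiers

Percent bound is 100·bound/(bound+unbound) per lane. Half-saturation is the
linearly interpolated first upward crossing of 50% — the quantity reported in
the source analysis is the crossing concentration, not a fitted binding
constant, so no Hill/cooperative model is fitted. Hydrolysis rates are
least-squares slopes, over all points by default with an optional time
window (no fit window is prescribed by the source).

## Synthetic data

All generators are pure functions of (config, seed).

**Quads.** Background site frequencies follow Beta(0.3, 3) (many rare, some
common); per-panel values jitter lognormally around the site frequency and
each panel omits a site with probability 0.05. Parental genotypes are
Hardy–Weinberg draws *conditioned on at least one parental carrier* — a union
of family variants contains no zero-carrier site — and children receive one
Mendelian allele per parent. Consequence classes follow a roughly
whole-genome-like mix (≈ 97% non-coding or synonymous), background predictor
calls are DAMAGING with probability 0.05 per tool, and noise is injected as
independent per-slot no-calls and symmetric allele flips at configured rates
(defaults 0). Planted causal variants are constructed exactly (de novo:
index het, others hom-ref; recessive: index hom-alt, parents het; compound
het: one paternal and one maternal variant in one gene), absent from all
panels, and DAMAGING in 3 of 4 tools. Defaults give 2,000 genes × 5 variants
= 10,000 background sites. The generator does not emulate read-level errors,
linkage, population structure or segmental variation, so passing tests show
correctness of the filtering logic under the stated genotype model, not
robustness to real sequencing artefacts.

**Clone panels.** A configurable fraction of clones is reverted with a
mechanism mix over {LOH retain WT, back mutation, LOH retain mutant}; each
mechanism fixes the four locus states, the unlinked DCHS2 control is retained
by default, and no-calls are injected per field. Defaults: 58 clones, 7/58
reverted, all LOH-retain-WT.

**Filament renders.** The backbone is a discrete 2-D worm-like chain sampled
at 2-nm arclength steps with angular deflections N(0, ds/Lp); persistence
length defaults to 200 nm coated and 50 nm bare — generator parameters, not
measurements. Coated stretches rise 0.51 nm/bp at 2.2 nm apex height, gaps
are bare DNA at 0.34 nm/bp and 0.5 nm apex. Gap intervals (default 90 bp
≈ 31 nm) are placed by the uniform-spacing construction with 150-bp end
margins and 80-bp separations; 90 bp is chosen because a gap must exceed
roughly twice the emulated tip radius before its floor drops below the 1-nm
threshold over ≥ 2 samples. Chains that leave the 1,500-nm field or
self-approach closer than 20 nm (which the tracer could not resolve) are
redrawn with bounded retries. The probe is emulated as a Gaussian ridge
cross-section (σ = 2 px) combined by maximum — a dilation-like model that
preserves apex height, as a real tip does — plus additive Gaussian noise
(default 0.15 nm). True tip-shape physics, sample drift and height
calibration error are not modelled.

**Curves.** Titrations are Hill-shaped (default coefficient 4, half-
saturation 0.3 μM, so binding is ~97% saturated at 0.8 μM) emitted as
bound/unbound lane intensities; time courses are linear with multiplicative
noise, clipped at zero.

## Problem sizes

The default verification runs use 25 renders per filament condition, 25
renders per planted gap count, and 100 seeded quads of 10,000 background
variants for end-to-end recovery; these sizes give stable means (s.e.m. well
inside every stated tolerance) while keeping the full suite around half a
minute.

## Known limitations

- The funnel consumes annotations, predictor scores and panel frequencies as
  inputs; no annotation or scoring engine is included.
- X-linked and imprinting models, mosaicism and read-backed phasing are out
  of scope; phase comes only from parental genotypes.
- The tracer assumes filaments do not cross themselves or each other;
  molecules violating the 20-nm resolvability margin would be mis-traced.
- Discontinuity counting is run-based; a definition counting individual
  sub-threshold samples would scale differently with sampling density.
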