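# fascreen

Tools for the computational side of a family-genomics study of a
Fanconi-anaemia-like disorder caused by a dominant-negative *RAD51* missense
allele: variant prioritization in a quad pedigree (father, mother, affected
index, unaffected sibling), classification of MMC-resistant revertant clones
by loss-of-heterozygosity vs back mutation, quantitative morphometry of
RAD51–DNA nucleoprotein filaments from scanning-force-microscopy (SFM) height
maps, and quantifiers for the accompanying biochemical readouts. Every input
the pipeline consumes can also be simulated with planted ground truth, so the
whole analysis is testable end to end.

## What it computes

**Variant funnel.** From the union of all small variants seen in any family
member, candidates are narrowed in fixed stages: (1) called high-quality in at
least one genome, (2) minor allele frequency ≤ 1% in every population panel
where the site is known (three panels by default; a site absent from all
panels passes — novel variants must survive), (3) the index patient is not
called homozygous reference, (4) protein-affecting consequence classes only
(non-synonymous, frameshift and non-frameshift indels/substitutions, stop
gain/loss, splice sites up to ±2 bases), then an inheritance model, then a
pathogenicity consensus requiring DAMAGING calls from ≥ 2 of 4 predictors
(SIFT, PolyPhen, MutationTaster, CADD — their scores are inputs, not
computed).

**Inheritance models.** Recessive homozygous (index hom-alt, both parents
het, sibling not hom-alt); compound heterozygous (two heterozygous variants
in one gene assignable to *different* parental genomes, both absent from the
sibling, uncalled alleles treated permissively); de novo (index het, all
other members confidently hom-ref — an uncalled parental allele disqualifies,
because a de novo claim needs positive evidence of absence). Relatedness
sanity checks use a robust genotype-concordance kinship estimator
φ = (N_hethet − 2·N_opphom) / (N_het,a + N_het,b) with the standard log2
degree bins (parent–offspring ≈ 0.25, unrelated < 2⁻¹⁰·⁵).

**Revertant clones.** Each MMC-resistant clone is genotyped at the RAD51
site, one flanking SNP in each of CASC5 and DNAJC17, and the unlinked DCHS2
control. Wild-type-only RAD51 with both flanking SNPs homozygous is LOH with
retention of the wild-type allele; flanking heterozygosity retained means
back mutation. The direction of LOH is formalized as a one-sided exact
binomial sign test P(X ≥ n_wt | n, ½).

**Filament morphometry.** RAD51 coats double-stranded DNA and extends it to
1.5× its B-form length (0.34 nm/bp → 0.51 nm/bp). Filaments are traced
automatically from calibrated height maps (threshold → skeletonize → longest
geodesic path → sub-pixel crest refinement → probe-broadening end
correction); per filament the pipeline reports contour length, mean height,
the extension ratio vs B-form, and coverage discontinuities (maximal runs of
≥ 2 trace samples below 1 nm). Group summaries are mean ± s.e.m.

**Biochemical quantifiers.** Percent DNA bound per EMSA lane, half-saturation
concentration by interpolation of the 50% crossing, ATP-hydrolysis rates and
their ssDNA stimulation ratio, and simple fold changes.

## Worked example

Simulate a quad with ~10,000 background variants and one planted de novo
damaging variant, then run the de novo branch of the funnel:

```sh
fascreen simulate-family --out sim --seed 42 --plant denovo
fascreen run-all --vcf sim/family.vcf --ped sim/pedigree.ped \
    --annotations sim/annotations.tsv --scores sim/scores.tsv \
    --frequencies sim/frequencies.tsv --out run --model denovo --seed 42
fascreen report --run-dir run
```

prints

```
[denovo]
  input                10001
  quality              10001
  frequency            3521
  proband_carrier      1765
  consequence          48
  model:denovo         1
  consensus            1
  candidate CAUSAL01 (DENOVO) 15:41000000G>A
```

— of 10,001 variants in the family union, 3,521 are rare in all panels,
1,765 are carried by the index, 48 are protein-affecting, and exactly one
(the planted variant) is absent from both parents and the sibling and
survives the 2-of-4 predictor consensus.

A clone panel with the study's reversion characteristics:

```sh
fascreen simulate-clones --out clones --seed 1
fascreen revertants --clones clones/clones.csv --out summary.json
```

reports 7 of 58 clones carrying only the wild-type RAD51 allele
(`fraction_reverted_percent: 12`), all 7 classified `LOH_RETAIN_WT` with the
DCHS2 control variant retained, and a direction test p-value of
(½)⁷ = 0.0078125 for observing 7 wild-type-only and 0 mutant-only clones
under no selective direction.

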