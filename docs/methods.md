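# Methods

This note records the models behind each frostmap module, the defaults and
why they were chosen, what the synthetic colonies do and do not emulate,
and the numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## The mapping problem

A single founder is heterozygous for a de novo semidominant allele.
Phenotype is scored visually in three classes and coded 0 (wild type),
1 (heterozygous mutant), 2 (homozygous mutant).  The colony is the founder
crossed to unrelated dams, plus carrier-by-carrier intercrosses and
carrier-to-dam backcrosses.  Because the reference is a fragmented draft
assembly, all analysis is done per scaffold, with synteny anchors
providing the only chromosome-scale order.

## Association arm

Model: `y = 1µ + g β + u + e` with `u ~ N(0, σg²K)`, `e ~ N(0, σe²I)`.

* **Marker filter.** MAF ≥ 0.05 and ≥ 10 hom-ref and ≥ 10 hom-alt
  individuals among non-missing calls.  The homozygote rule is read as a
  requirement on *both* allele classes (the stricter of the two possible
  readings) and is configurable (`FilterConfig.min_hom`).  Per-sample
  calls failing DP ≥ 30 or GQ ≥ 30 are set to missing rather than the
  record being dropped.
* **Kinship.** VanRaden centred cross-product,
  `K = WWᵀ/(2Σpⱼ(1−pⱼ))`, on per-marker mean-imputed dosages.  Markers
  with zero variance after imputation contribute nothing and are skipped
  with a warning.  No shrinkage is applied.
* **REML.** `K = USUᵀ` once; the profile REML log-likelihood in
  λ = σg²/σe² is evaluated on a 61-point grid of log₁₀λ ∈ [−5, 5] and the
  bracket around the best grid point refined by bounded scalar
  minimisation.  Fixed effects: intercept only.
* **Scan (P3D).** λ is frozen at its null estimate; each marker is tested
  by GLS in the whitened basis `(λS + I)^{-1/2}Uᵀ` with a Wald t-test on
  the dosage coefficient, df = n − 2, residual variance re-estimated per
  marker.  With λ = 0 this is algebraically identical to OLS (verified
  against statsmodels to 1e-8 relative).  Markers monomorphic after
  imputation are reported untested.
* **Multiple testing.** Galwey's `M_eff = (Σ√λᵢ)²/Σλᵢ` over the
  eigenvalues of the marker correlation matrix; eigenvalues are clipped at
  0 and values below 1e-10 of the largest are zeroed (rank-deficiency
  noise otherwise inflates Σ√λ).  Threshold: α/M_eff, compared strictly
  (`p < thr`).  p-values are floored at the smallest positive double so a
  perfectly separating marker reports p > 0 rather than 0.

Degenerate regime worth knowing: when phenotype equals causal dosage
exactly (the default, noiseless scoring) and the causal marker is in the
panel, the null REML drives λ to its upper search bound and the causal
marker's residuals vanish; the scan then reports the p floor for that
marker.  This is the intended behaviour, not an error.

## Homozygosity-mapping arm

Founder-het markers are selected by: biallelic, founder genotype het,
founder allele balance alt/(ref+alt) ∈ [0.4, 0.6] *inclusive at both ends*
(the depth rule "DP ≥ 30" is written inclusively, so the balance range is
read the same way), founder DP ≥ 30 and GQ ≥ 30, scaffold length ≥ 5 kb.
Balance uses AD rather than alt/DP so clipped or third-allele reads cannot
bias it.  Multi-allelic records are dropped whole, not split.

Concordance of a variant: het-pool AF and founder AF in [0.4, 0.6]
(inclusive), hom-pool AF > 0.85 (strict), wild-type AF < 0.15 (strict).
The founder's AF is re-evaluated from his WGS read counts at this stage
rather than inherited from the genotyping filter.  Any pool (founder
included) under 30 reads, or with no reads, makes the variant
uninformative — excluded from numerator *and* denominator, since the
window statistic is a fraction over usable markers.  GQ is not defined for
pools, so pools are gated on depth only.

Windows are non-overlapping 10 kb tiles anchored at scaffold coordinate 0
("every 10 kb interval" read as tiling, not sliding).  Windows with fewer
than 5 informative variants are reported but flagged non-qualifying and
excluded from ranking.  Ranking is by fraction, ties broken by more
informative variants, then scaffold name, then start.

**Resolution limit (measured, and worth stating plainly).**  With two to
three meioses separating pool members from the founder, every 10 kb window
within roughly ±0.06 Morgans of the mutation has the *same* expected
fraction: the hom-pool bound AF > 0.85 tolerates about 7 recombinant
haplotypes among 50, so nothing distinguishes the causal window from its
plateau neighbours except het-pool binomial read noise at 30x
(P(AF ∈ [0.4, 0.6]) ≈ 0.7 per variant).  Consequently the top-ranked
single window lands on the exact causal window only ~20% of the time in
replicate colonies, while the plateau as a whole is found in every
replicate (near-causal mean fraction beats the genome-wide mean in 20/20
seeds; the top window always falls inside the linked region).  The method
localises a neighbourhood, not a window; interpret the peak accordingly.

## Synteny and LD

Projection: with ≥ 2 anchors on a scaffold, piecewise-linear interpolation
between anchors and linear extrapolation beyond the outermost pair, with
orientation from the anchor slope; a single anchor places the whole
scaffold at one reference point with unknown orientation; anchors
disagreeing on the reference chromosome are resolved by majority with a
warning; unanchored scaffolds stay unplaced.  Projecting the anchors
themselves reproduces their reference coordinates exactly.

LD is genotype-correlation r² (composite LD; colony VCFs are unphased) on
pairwise-complete observations; monomorphic markers get missing r².  The
decay statistic is Spearman's ρ between pairwise projected distance and
r².  Its p-value permutes *marker labels* of the LD matrix (Mantel-style,
default 10,000 permutations, seeded), which preserves the dependence of
the (m choose 2) pairs; permuting pairs independently would overstate
significance.  The implementation is cross-checked against scikit-bio's
Mantel test.  Pairs involving unplaced markers are dropped.

## Synthetic colonies

The generator reproduces the statistical structure the analysis assumes,
at desk scale: a 20 Mb genome as 5 chromosomes of 4 Mb tiled by ~40
scaffolds each (uniform random cuts, so scaffold lengths are roughly
exponential with mean 100 kb and a few under the 5 kb cutoff; random
orientations; shuffled names), a 511-animal colony (12 dams × 14 F1,
12 intercross families × 20, 6 backcross families × 15), 188 genotyped
animals in a 39/116/33 wt/het/hom split, and 25/63/71 pools at 30x.

Choices that need justification:

* **Genetic map: 1.25 Morgans per chromosome.**  The 20 Mb genome stands
  in for a ~2 Gb, ~19-chromosome genome; the biologically conserved
  quantity is ~1–2 crossovers per chromosome per meiosis, so per-
  chromosome map length is preserved rather than cM/Mb.  Exposed in
  config; nothing downstream assumes it.
* **Background variation.**  Founder-pool haplotypes carry (i) common
  variants at density 1/400 bp with Beta(0.5, 2) frequencies, (ii)
  variants private to the mutation-bearing founder haplotype at
  1/200 bp — the founder comes from a line diverged from both the
  reference assembly and the dam stock, which is exactly what makes his
  heterozygous sites informative pool markers — and (iii) per-haplotype
  private variants at 1/5000 bp.  Together: founder-het density ≈ 1/170 bp,
  leaving ~12 informative variants per 10 kb window after depth filtering,
  the same order as the ~22 usable variants the design targets per window.
* **Depth model.**  Per-site depth is Poisson(coverage × m) with a
  Gamma(6) site factor m *shared across the founder and all pools*:
  sequencing depth at a site is strongly correlated between libraries
  through mappability, and with independent Poisson depths the joint
  P(all four ≥ 30 reads) would be an unrealistic 0.08 instead of ~0.3.
* **Genotype calling.**  Reads flip allele with a fixed error rate
  (RAD 0.005, pools 0.002); calls are maximum likelihood over
  {hom-ref, het, hom-alt}; GQ is the phred-scaled log₁₀-likelihood gap to
  the runner-up, capped at 99; depth 0 is a missing call.  RAD loci are
  sequenced at mean 60x (reduced-representation panels concentrate depth
  on few loci), so per-sample DP/GQ masking removes little.
* **Causal site in the RAD panel.**  Included by default so the scan's
  best case — a marker in complete dosage-phenotype concordance — exists
  in every run; turn off `RadModel.include_causal` for the harder variant.
* **Gene dropping conditioned on the pedigree.**  Crossovers are drawn
  unconditionally and the starting phase chosen to match the recorded
  causal transmission — the exact conditional distribution given the
  transmitted allele — so pedigree dosages and haplotype mosaics never
  disagree.
* **Phenotype = causal dosage** with an optional misclassification rate
  (default 0); phenotypes were scored visually in the motivating design,
  and the hook allows scoring noise without touching the genetics.

What the simulator does *not* emulate: read alignment artefacts, indels
(all variants are SNVs with decorative bases), reference bias, sex
chromosomes, crossover interference, linked selection, and identity-by-
state sharing between the founder's mutant haplotype and dam haplotypes.
The last item matters for interpretation: in real data, IBS sharing makes
some founder-het variants discordant even at zero genetic distance, so
real near-causal fractions (~0.9) sit below 1 for an additional reason the
simulator does not model.  Passing tests therefore demonstrate the
statistical machinery — filters, scan calibration, window statistic,
ranking, LD decay — under the design's sample sizes and noise, not
robustness to alignment- or ascertainment-driven artefacts.

## Reproducibility mechanics

One run seed fans out through `numpy.random.SeedSequence.spawn` to the
colony (which itself spawns ten stage streams: genome, pedigree,
background variants, gene drop, RAD sites, RAD reads, pool reads, panel
assignment, anchors, phenotype noise) and to the LD permutation stream, so
stages can be re-run in isolation and a fixed seed reproduces every output
file byte for byte.  All intermediates are plain VCF v4.2 / TSV / BED.
Problem sizes in the shipped tests and the acceptance script (default
scenario, 10–20 replicate colonies, 2,000-marker calibration panels) were
chosen to keep a full run on one CPU in the minutes range while leaving
every distributional check at its stated tolerance.
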