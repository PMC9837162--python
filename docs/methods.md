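# Methods

## Problem and model

`tatakd` estimates the equilibrium dissociation constant (KD) of the
complex between plant TATA-binding protein (TBP) and a 90 bp proximal
promoter, then asks whether promoters of genes homologous to the wheat
allergens globulin, albumin and β-amylase bind TBP more weakly in food
than in non-food plant species.

TBP binding is modelled in three steps: (i) nonspecific sliding along
the double helix, characterised by KD ≈ 10⁻⁵ M; (ii) arrest at a
TATA-like site recognised through a position weight matrix (PWM);
(iii) stabilisation of the complex by bending of the DNA axis.  The
package implements a calibrated surrogate of this mechanism: step (i)
fixes the affinity ceiling at the nonspecific anchor, step (ii) is
PWM log-odds recognition, and step (iii)'s stabilisation is absorbed
into a linear interpolation in ln KD between the two anchors,

    ln KD = ln KD_ns + s* (ln KD_sp − ln KD_ns),

where KD_ns = 10⁻⁵ M, KD_sp = 10⁻⁹ M, and s* ∈ [0, 1] is the best
window's normalised recognition score: the log-odds score of the
window (against a uniform background) divided by the consensus score,
clipped below at zero.  Clipping encodes that a background-level
window cannot outcompete nonspecific sliding; the promoter KD is set
by the single best window on either strand — the maximum-occupancy
site at which TBP stops — not by a partition-function sum, which would
be dominated by the ~150 nonspecific windows and break the anchors.
Consequently KD is always within [10⁻⁹, 10⁻⁵] M (1–10⁴ nM), exact at
both endpoints, and identical for a sequence and its reverse
complement.  Ties between windows are resolved deterministically:
forward strand first, then the smaller 1-based start.

No claim is made that these KD values reproduce any particular
laboratory or web-service estimator in absolute terms; the surrogate
preserves the mechanism's ordering and calibration anchors, and all
downstream statistics are agnostic to this substitution.

## The TATA matrix

The packaged default is a 15-column position frequency matrix built
from the canonical TATAWAWR core (columns 4–11): consensus base 0.85
with off-consensus bases at 0.05; W columns split A/T at 0.45 each;
the R column splits A/G at 0.45 each.  Flanking columns are uniform —
they contribute zero log-odds, so the consensus score is defined
entirely by the core; making them exactly uniform (rather than mildly
informative) keeps the score lattice simple and avoids spurious tie
structure.  Matrices are loaded from a plain-text 4-row (A, C, G, T)
table of counts or probabilities; each column is renormalised after
adding a pseudocount (default 0.01), so a zero count never produces a
−∞ log-odds and an all-zero column degrades gracefully to uniform.
Any matrix of width ≥ 6 can be swapped in via configuration.

## Cohorts and filtering

Promoters are exactly 90 bp, stored 5'→3' with position 90 adjacent to
the transcription start site; the provided 90-mer is treated as
authoritative and never re-anchored.  Records carry species, gene
family (globulin / albumin / beta_amylase) and group (food /
non_food).  Sequences are uppercased and U→T mapped on input; records
containing IUPAC ambiguity codes (R, Y, W, S, K, M, B, D, H, V, N) are
excluded from scoring and listed in the run log, mirroring the
exclusion of sequences with unknown nucleotides from the reference
cohorts.  Any other character is a hard validation error.

## Group statistics

Per-promoter KD values are reported in nM.  A group summary is the
promoter count N, arithmetic mean M0 and standard error of the mean
(sample SD with n−1 denominator over √n).  Group-level averages pool
promoters rather than species means, because the published group N
equals the promoter count; `species_weighted=True` switches to
averaging species means.  Two groups are compared with the
difference-of-means Z-test,

    Z = |M0₁ − M0₂| / √(SEM₁² + SEM₂²),

referred to the standard normal, two-sided.  Applied to the packaged
published group summaries this reproduces the reference statistics:
globulin Z = 3.65, albumin Z = 3.81, β-amylase Z = 2.72 (published as
3.59, 3.85 and 2.74 from less-rounded inputs).  The three family
tests are uncorrected by default (the reference analysis reports three
uncorrected tests); a Bonferroni ×3 option exists.  Significance is
annotated with the star ladder *** p<0.001, ** p<0.01, * p<0.05.
With both SEMs zero the statistic is undefined (equal means → error;
unequal means → Z = +∞ with p = 0, logged).

## Synthetic cohorts

The generator emulates the structure of the study cohorts without any
database retrieval.  Each record is an i.i.d. background sequence with
a GC-content knob (default 0.40, a typical plant promoter
composition), carrying one planted TATA-like site whose normalised
score is drawn from a normal distribution truncated to [0, 1]
(group-specific mean, common SD), realised by greedy single-base
degradation of the consensus window.  Scores live on a discrete
lattice (each substitution moves the score by a fixed decrement), so
the achieved site score is within one substitution step of its target.
The site is placed uniformly so its span lies within positions 21–70
of the 90-mer, i.e. centres between −70 and −20 relative to the
transcription start site, where functional TATA boxes concentrate.
One site is planted per promoter, since the affinity model only uses
the best window.  Defaults: 50 promoters per group over 10 species
each, one gene family, planted strengths 0.4 (food) vs 0.8 (non-food)
with SD 0.1 — the food group weaker, hence larger KD, matching the
direction of the published food vs non-food difference.  Generation
uses NumPy's PCG64 generator; the integer seed is recorded in the
cohort provenance and identical spec + seed reproduce the cohort
byte-for-byte.

## Validation studies and problem sizes

The test suite validates the pipeline at these scales, chosen as the
package's standard validation conditions:

* scanner vs exhaustive enumeration on 200 random 90-mers with a
  width-6 matrix; strand symmetry on 500 random 90-mers;
* type-I error: 2000 replicate null cohorts (equal planted strengths
  0.6, n=50/group); measured rejection rate at p<0.05 is 0.052,
  inside the 99% binomial band around 0.05 ([0.0375, 0.0625]);
* power: 200 replicate cohorts at the default planted effect;
  measured rejection rate at p<0.01 is 0.815 (0.848 ± 0.015 over 600
  replicates), with the food group's mean KD larger in every
  replicate.

## Limitations

* **Background masking bounds the power of the planted effect.**  The
  TATAWAWR core accepts A at high probability in six of its eight
  positions, so AT-rich random background (GC 0.40) frequently
  contains strong spurious windows: ~48% of site-free 90-mers score
  ≥ 0.654 (one substitution from consensus) and ~5.5% contain a
  chance-perfect core.  The best-window statistic therefore masks
  weakly planted sites: the food group's realised scores are pulled up
  toward the background maximum, compressing the planted 0.4-vs-0.8
  effect, while the unmasked minority of weak sites produce KD
  outliers (up to ~3×10³ nM) that inflate the food group's SEM on the
  arithmetic-mean nM scale.  Under these study conditions the
  two-group test detects the default effect at p<0.01 in ~85% of
  replicates, not more; detection at p<0.05 is ~94%.  This is a
  property of TATA-like motifs in AT-rich DNA, not of the scanner
  (which is verified exhaustively), and it equally affects both groups
  under the null, where calibration is correct.
* The i.i.d. background has no dinucleotide structure, indels or
  phylogenetic correlation between species; passing tests demonstrate
  the statistical machinery, not realism of plant promoter evolution.
* The truncated-normal site-strength distribution is a modelling
  convenience; the real distribution of site strengths in plant
  promoters is unknown.
* Species are treated as exchangeable; no phylogenetic correction is
  applied to the group comparison (promoters from related species are
  not independent in real data).
* The surrogate KD estimator is calibrated only at its two anchors;
  absolute intermediate values depend on the linear-in-ln-KD
  interpolation and the matrix, and should be interpreted as ordering
  scores on a physically meaningful scale rather than measured
  affinities.

## Numerical choices

Natural logarithms throughout; KD is carried in mol/L internally and
reported in nM.  The endpoint scores 0 and 1 return the anchors
exactly (no exp/log round-trip).  Strand/position ties use a 10⁻¹²
absolute tolerance.  Probability columns must sum to 1 within 10⁻⁹
after pseudocount normalisation.  Output tables format floats with
%.6g and contain no timestamps, making report bundles byte-stable
under reruns.
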