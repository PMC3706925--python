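# Methods

## Observation model

Plasma cfDNA is modeled as a two-component mixture: a maternal component of
weight 1−f and a fetal component of weight f, with f the fetal fraction.
At a biallelic marker the expected alt-read fraction is

    theta = (1−f)·g_M/2 + f·g_F/2                  (autosome)

where g_M ∈ {0,1,2} is the maternal alt dosage and g_F the fetal dosage
implied by the transmitted parental alleles.  A male fetus carries a single
maternal X, so on chrX the fetal component contributes one haplotype out of
a total of 2−f genome equivalents:

    theta_X = [(1−f)·g_M + f·a_m] / (2−f)

with a_m the transmitted maternal X allele; X depth is correspondingly
scaled by (2−f)/2.  Sequencing error is a symmetric per-read flip with
probability eps, giving theta_err = theta(1−eps) + (1−theta)eps.  Read
counts are binomial in theta_err given the site depth.  This count-level
binomial is the minimal observation law consistent with per-site allele
counts; it ignores read-level base qualities and GC/fragment-length
structure.

## Hidden chain

Per chromosome, the sites where at least one parent is heterozygous
(paternal-only, maternal-only, biparental het) form the chain; states are
the transmitted haplotype indices (h_p, h_m) — four autosomal states, two
on a male fetus's X.  Transitions factor over the two independent meioses;
each parent's switch probability over an inter-site gap of d Morgans is the
Haldane (no-interference) map rho = (1−e^(−2d))/2, with d from a constant
per-genome cM/Mb rate.  The initial distribution is uniform.  Decoding is
exact Viterbi in natural-log space with deterministic tie-breaking (prefer
no switch, then the lower state index); per-site transmission posteriors
come from forward–backward and are reported as natural-log odds of
haplotype 1 versus haplotype 0 per parent.  Breakpoints are reported as the
interval between the last informative site before and the first after a
decoded switch.  Sites where both parents are homozygous are excluded from
the chain: their fetal genotype is implied by the parental genotypes alone.
Sites with zero depth contribute emission 0 for every state and are carried
by the transition structure.

## Fetal-fraction estimation

At discordant-homozygous sites (mother hom for one allele, father for the
other) every read carrying the paternal allele is fetal, with expected
fraction f/2 before error.  Pooling reads across qualifying sites
(depth ≥ min_depth, default 1) gives the method-of-moments estimator

    f_hat = 2·(p_hat − eps) / (1 − 2·eps),  clipped to [0, 1]

with p_hat the pooled paternal-allele read fraction; eps = 0 disables the
error correction.  Per-chromosome estimates use the same formula per
chromosome.  For a male fetus the X carries no paternal transmission, so
estimation is effectively autosomal.

## Parental phasing

A parent is phased against its own two parents by Mendelian logic per
site; the assignment of the parent's alleles to grandfather/grandmother
origin is forced at most sites, ambiguous where both orientations are
compatible (e.g. all three heterozygous), and flagged where transmission is
impossible (input error).  Remaining ambiguous het sites are completed
against a phased reference panel: each panel haplotype is matched to the
two partial parental haplotypes over the nearest 10 phased het sites and
votes its allele onto the better-matching side, weighted by the match
margin (the weighting prevents a related haplotype that is homozygous
across the window from cancelling the informative vote); ties fall back to
a seeded coin flip, and the phase source (trio / panel / random) is
recorded per site.  This windowed-vote completer deliberately replaces
population-scale statistical phasing at desk scale; it preserves the
interface — partial trio phase in, complete phase out — not imputation-
grade accuracy.  Switch-error rate is counted over consecutive het pairs
as phase flips against truth, which makes it invariant to the global
haplotype labeling.

## Synthetic-data generator

The generator emulates the study design: four diploid grandparents drawn
site-independently from per-site alt frequencies ~ U(0.05, 0.95) (an
array-ascertainment stand-in), parents formed by one meiosis per
grandparent, the fetus by one meiosis per parent.  Crossover counts per
chromosome are Poisson with mean L_Mb·r/100 (Haldane, no interference),
positions uniform; hemizygous X passes without recombination, and a male
fetus receives a recombinant maternal X only.  Plasma depth is Poisson
(optionally fixed for analytic tests) and counts are binomial in theta_err
exactly as the HMM assumes.  Defaults are the study regime: f = 5.69%,
mean non-duplicate depth 33.6X, eps = 0.005, 1.2 cM/Mb for both parental
maps, male fetus, ~370,000 autosomal markers length-scaled over the 22
autosomes.  chrX carries 5,200 markers by default — chosen so the
maternal-het X count is ~1,900, the sparse X coverage regime of the
motivating study — rather than the ~19,000 pure length-scaling would give.
A de-novo spiker flips one fetal allele to the non-parental allele at
selected biparentally-uninformative sites for baseline sensitivity tests.

What the generator does not emulate: linkage disequilibrium between
markers (except optionally in phasing-panel tests, where the pedigree's own
haplotypes serve as the panel), GC and mappability structure, fragment-size
differences between fetal and maternal cfDNA, duplicate reads, and
real-data phasing noise.  Passing accuracy bounds here therefore shows the
decoder performs correctly when its model holds — with error-free parental
phase, which the real study did not have; it does not bound performance
under array genotyping error or imperfect phasing.

## Numerical and design choices

- All probability arithmetic in natural-log space; forward–backward uses
  max-shifted log-sum-exp.  Posterior normalization is exact to < 1e-9
  (checked against brute-force path enumeration on small chains).
- Emission theta is clipped to [1e-12, 1−1e-12]; transition probabilities
  to ≥ 1e-300 before the log (rho = 0 at zero distance is otherwise exact).
- Viterbi ties are broken toward the previous state then the lower index,
  making decoding fully deterministic; with no data the path is constant.
- Depth law Poisson with a fixed-depth switch; the non-duplicate mean is
  the depth parameter.
- Positions are 1-based at all external interfaces (VCF/TSV); BED output
  is 0-based half-open.  Counts align to the parental site list by
  (chrom, pos); a ref/alt disagreement at a shared position is a hard
  error, an absent site is zero-count.
- Mendelian-inconsistent trio sites are excluded from phase inference and
  flagged; plasma counts incompatible with the parents are *not* filtered
  before decoding — the binomial error term absorbs them.
- Error taxonomy windows: type III regions default to the first/last 1 Mb
  of each chromosome (plus any user BED); type II is within 1 Mb of a true
  or inferred breakpoint; precedence III > II > I.

## Problem sizes used by the test suite and acceptance script

The acceptance script and the headline bounds run the full default genome
(~375k markers) for three replicate seeds, ~10 s per replicate on one CPU.
Unit and property tests use subsets (2–4 chromosomes, 1.5k–260k sites)
chosen per test so that closed-form oracles have ≤ 3-SE Monte-Carlo
resolution; the downsampling curve runs on a four-chromosome subset at
fractions {0.06, 0.25, 0.5, 1.0}.

## Known limitations

- chrX accuracy is breakpoint-limited in the default regime: ~1,900
  maternal-het X markers over 155 Mb give ~0.056 nats of per-site evidence
  at f = 5.69% and 33.6X·(2−f)/2, so each maternal X crossover (≈1.9
  expected at 1.2 cM/Mb) is localized only to within tens of markers, and
  a close crossover pair can fall below the two-switch penalty and be
  missed entirely.  Expected X allele accuracy is ~97% across seeds (median
  ~99%), lower than the autosomal maternal accuracy despite the cleaner
  2-state chain.  This is an information limit of the operating point, not
  a decoder defect: Viterbi is exact and the emissions match the generative
  law.  Denser X markers or higher depth remove it.
- The HMM has no de-novo mutation state; de-novo detection is only the
  naive SBSS scan, whose sensitivity at depth n is 1−(1−f/2)^n and whose
  specificity against PCR/sequencing artifacts is not modeled.
- Biallelic SNVs only; multi-allelic records and indels are dropped on
  input.  chrY and mitochondrial sites are out of scope.
- The panel completer is not an imputation engine; with an uninformative
  panel it degrades to seeded coin flips (reported as such per site).
- Twin pregnancies, trisomy detection and maternal copy-number variation
  are outside the model.
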