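# Methods

`preselsim` simulates a closed broiler nucleus breeding program and measures
how the criterion and intensity of *preselection* — the early culling stage
that decides which chicks are ever phenotyped for late traits and genotyped —
shape the quality of genomic breeding values at final selection and the
genetic progress they deliver. This note documents the model, the
synthetic-data generator, the numerical choices, and what the package's
tests do and do not demonstrate.

## Genome and founder population

Loci are abstract biallelic sites on a genetic map. The full-scale (`full`
profile) genome has 28 chromosomes between 45 and 484 cM, 2930 cM in total,
mirroring the span of the chicken genome. Per-chromosome locus counts are
proportional to map length and positions are uniform; the exact
per-chromosome length vector is a configuration choice — any decreasing
vector within that range summing to the same total is equivalent for the
questions the simulator addresses.

The historical population establishes mutation–drift equilibrium: both
alleles start at frequency exactly 0.5 at every locus, then the population
(1000 birds at full scale; 200 in the desk profile) mates randomly for 1000
(desk: 200) generations with no selection or migration and a recurrent
mutation rate of 2.5×10⁻⁸ per locus per meiosis. Recombination follows the
Haldane model — crossover count per chromosome ~ Poisson(length/100),
positions uniform, no interference — which is the standard choice when no
interference model is specified.

Founder expansion re-samples 50 males and 50 females (desk: 25+25) each
generation for seven generations, each random pair producing ten offspring,
so each expansion generation holds 500 individuals. The base population is
built by giving each of 320 males and 4800 females (desk: 40 + 240) one
haplotype from each of two distinct random founders. Marker (52k; desk 2k)
and QTL (3k; desk 200) panels are drawn uniformly without replacement from
the loci segregating at MAF ≥ 0.05, disjointly. Base-population allele
frequencies are frozen at this point and reused for all later G-matrix
centering, which keeps G compatible with the pedigree relationships.

## Traits

Three traits with phenotypic variance 1: body weight (BW, h² = 0.18),
residual feed intake (RFI, h² = 0.19) and gain (h² = 0.17). Genetic
correlations (BW–RFI 0.11, BW–Gain 0.15, RFI–Gain 0.14) give
V_g = diag(σ_g) R_g diag(σ_g) with σ_g,t = √h²_t. Residual correlations
(−0.08, 0.07, −0.04) act on residual variances 1 − h² (minus c² = 0.04 for
BW, the maternal permanent-environment fraction). QTL effects are drawn iid
N(0,1) per trait and then linearly transformed (symmetric square-root
whitening and re-coloring, with TBVs centered) so that base-population true
breeding values have mean exactly zero and empirical covariance exactly V_g;
the effects are then frozen for the whole scheme. Centering the TBVs rather
than the genotype columns is covariance-equivalent and makes the base mean
exactly zero.

Phenotypes are y = x + b_hatch + g + c_dam·[BW] + e with e ~ MVN(0, R) per
animal, one hatch effect per hatch × trait × round drawn with variance equal
to 2% of phenotypic variance (hatch variance between 1% and 3% is realistic
for broiler flocks; the default sits at the midpoint and is configurable
per trait), and one maternal PE value per dam ~ N(0, 0.04) applied to all
her chicks' BW. Hatch variance is added on top of the unit phenotypic
variance because the residual covariance formula leaves no room for a
hatch share. The contemporary-group effect x defaults to zero: it has no
well-defined magnitude in this design and is absent from the estimation
model; a hook exists to enable it as a fixed shift.

## Breeding scheme

Each selection round: 9000 chicks (desk: 600) hatch in 7 hatches with an
exact 50:50 sex ratio; BW is recorded on all; a per-sex fraction is
preselected on either the BW phenotype (criterion P), a BLUP index (B) or an
ssGBLUP index (G); the preselected are phenotyped for RFI/Gain and
genotyped; 10 sires and 150 dams (desk: 4 + 40) are chosen from the
preselected on the final ssGBLUP index; each sire is mated to 15 fixed dams
(desk: 10) and the cohort reproduces over the next four rounds with litter
sizes 16, 16, 15, 13 chicks per dam (desk: 4, 4, 4, 3), then retires. Four
overlapping parent cohorts therefore produce each round's chicks
(150 × 60 / 4 stages at full scale). Chicks are interleaved dam-major into
hatches so hatch sizes differ by at most one and full-sib families spread
across hatches. Ties in any truncation are broken by ascending id.

Bootstrapping: one random base parent set (10♂ + 150♀) occupies all four
cohort slots initially and phases out over the first four rounds as
selected cohorts mature — a single parent set reused across the early
rounds rather than four independently drawn ones.

Preselection intensities: 10:30%, 15:45%, 20:60% of males:females
(strategies P10…G20). The selection index is
H = 1·(EBV_BW/σ_BW) − 0.82·(EBV_RFI/σ_RFI) + 0.50·(EBV_Gain/σ_Gain).

## Evaluation model

A three-trait animal model y = Xb + Zg + Wc + e with hatch × trait fixed
effects, breeding values g ~ MVN(0, K ⊗ V_g) with K = A (BLUP) or H
(ssGBLUP), maternal PE c ~ N(0, I·0.04) on BW only, and e ~ MVN(0, I ⊗ R).
True (simulated) variance components are used throughout; nothing is
estimated. Records with missing traits (RFI/Gain exist only for preselected
birds) are weighted by the inverse of the observed sub-block of R — the
exact multivariate treatment, not a single-trait approximation.

H⁻¹ = A⁻¹ + block(G*⁻¹ − A22⁻¹) on the genotyped animals, with
G* = 0.95 G + 0.05 A22, G the VanRaden method-1 matrix centered on the
frozen base frequencies (markers monomorphic in the base are excluded from
Z and the denominator), A22 the pedigree relationships among genotyped
animals, and inbreeding included in A⁻¹ (Henderson's rules with
Meuwissen–Luo / tabular inbreeding). Every evaluation uses all records
since round 1; at preselection the current cohort is un-genotyped and its
GEBVs flow through pedigree links to genotyped parents, exactly as in
practice.

### Numerical choices

* The mixed-model equations are solved matrix-free by preconditioned
  conjugate gradients to a relative residual below 10⁻⁸ (configurable).
  The preconditioner is an exact sparse LU factorization of the MME
  *without* the dense genomic correction — a direct solve for BLUP, and a
  strong preconditioner for ssGBLUP that leaves only the genomic coupling
  to the iteration (typically ≈100 iterations). A block-Jacobi (3×3 per
  level) fallback exists and is cross-checked in tests. Warm starts from
  the previous round's solutions are used as initial guesses only.
* No intercept is fitted; the hatch partition is itself full rank, so no
  explicit zero constraint is needed. Hatch × trait cells without records
  are pinned to zero.
* A is grown incrementally by the tabular method as cohorts hatch (new
  relationship rows are linear in existing ones since parents always
  precede offspring); inbreeding is read off the diagonal. A22 and G* only
  ever gain rows, so their inverses are extended by bordered
  Schur-complement updates instead of full re-inversions; first inversions
  are verified by probe-vector residuals and a cheap 1-norm condition
  estimate, failing loudly rather than silently regularizing beyond the
  0.95/0.05 blend.
* All randomness flows from one master seed through hierarchical
  `SeedSequence` streams (replicate → setup → scheme), so every output is
  bit-identical under a fixed seed.

## Measured quantities

Per round and replicate: preselection accuracy (correlation of TBV with the
preselection EBV/GEBV over the whole cohort, defined for B and G),
final-selection accuracy and dispersion regression RC (slope of TBV on
GEBV) over that round's preselected candidates, and dam-family counts among
preselected and selected candidates per sex. Statistics are averaged over a
window of late rounds within replicate, then over replicates, with
SE = sd/√n over replicate means. Genetic progress is the change in mean
standardized TBV (or GEBV) of final-selection candidates between two
rounds, per trait and for the index; progress overestimation is
100·(Δ_GEBV − Δ_TBV)/Δ_TBV. Strategy contrasts use two-sided Welch t-tests
on replicate-level values (the unequal-variance form is the safe default
when only a "t-test" is specified). At full scale the window is rounds
30–40 (inclusive, 11 rounds) with progress between rounds 30 and 40.

## Desk scale and what the tests show

The full-scale program (9000 chicks × 40 rounds × 15 replicates × 52k
markers) is a cluster-sized computation. The package's own experiments run
the `desk` profile: a 3-chromosome 300 cM genome, 200-generation history of
200 birds, 2000 markers + 200 QTL, 600 chicks/round, 4 sires + 40 dams, 10
rounds, 10 replicates, with statistics over rounds 6–10 and progress
between rounds 5 and 10. Desk replicates share one historical pool and
draw independent founder expansions, panels, base populations, QTL effects
and scheme streams; strategies are compared with common random numbers
(paired replicate seeds).

At this scale the tests demonstrate (i) exact structural bookkeeping of the
scheme, (ii) agreement of every relationship matrix and MME solution with
dense brute-force oracles, (iii) null calibration — with no preselection
the pipeline's GEBVs are unbiased (mean RC ≈ 1) and GEBV-based progress
tracks TBV-based progress — and (iv) directional preselection effects:
genomic preselection is more accurate than BLUP preselection for RFI
(paired sign test), and phenotypic preselection inflates BW GEBVs (lowest
RC). Desk-scale magnitudes are not the full-scale magnitudes: smaller
cohorts, fewer markers and a shorter history weaken LD and family
structure, so accuracies and biases differ quantitatively from a full-scale
run even where the orderings are preserved.

One full-scale ordering is *not* preserved at desk scale, and deliberately
so documented: the deficit in windowed index progress under phenotypic
preselection. With 200 QTL and 4 sires per round, selection exhausts
genetic variance within ~15 rounds (cohort BW genetic SD falls from 0.42
to ≈0.13–0.21), and the more accurate index-based selectors consume
variance fastest, which compresses their late-window progress relative to
P. The cumulative effect — a higher index *level* under G than under P at
every horizon — matches the full-scale steady-state ordering, but the
windowed Δ statistic inverts, and longer desk horizons strengthen the
inversion. The corresponding acceptance test is left failing rather than
re-targeted; reproducing that Δ contrast requires something closer to the
full-scale genome and effective population size.

## Limitations

* Strictly additive QTL; no dominance, epistasis or G×E.
* No variance-component estimation (the true simulated components are used
  by design), no reliabilities/PEV.
* No metafounders, unknown-parent groups or APY approximation in H⁻¹.
* The simulator does not emit nucleotide sequence; loci are abstract sites.
* Mating is a fixed random 1:15 allocation; no inbreeding-minimizing or
  assortative designs.
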