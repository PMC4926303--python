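# Methods

## Population and timeline

A closed nucleus with discrete selection rounds. Founders (generation −5)
are 250 bulls and 50 000 cows at full scale. Each round, every active dam
produces one progeny (sex Bernoulli ½) by a randomly assigned active sire;
sires are used equally (the dams are permuted and split into equal blocks,
remainder matings going one-per-sire to the lowest-id sires). The dam herd
grows by 12.5 % per round over the five pre-generations and is capped at
75 000 the first time the cap is exceeded (50 000 → 56 250 → 63 281 →
71 191 → 75 000); the printed growth rate and the constant herd size are
arithmetically inconsistent over five rounds, and we treat the cap as the
binding constant. Thereafter the active population is exactly 250 sires and
75 000 dams. Thirty rounds are simulated: cohorts −4…0 (pre-phase,
unweighted selection) and 1…25 (selection on both traits). Polled genotypes
are assigned in the generation-0 progeny cohort, and weighting starts with
the selection round that screens that cohort.

## Quantitative trait

Infinitesimal model, female sex-limited, h² = 0.3 on phenotypic variance 1.
The genetic SD is taken literally as the printed 0.54 (the rounding of
√0.3), so var_a = 0.2916, var_e = 0.7084 and the BLUP ratio
λ = var_e/var_a ≈ 2.4294 is derived from those constants. Founder TBVs are
N(0, 0.2916). Progeny TBV = mid-parent + m with
Var(m) = ½·var_a·(1 − (F_s + F_d)/2): Mendelian-sampling variance shrinks
with parental inbreeding, as in standard pedigree simulators. Phenotypes are
recorded once, at birth, for females only; the overall mean μ is 0 (the
animal model estimates a mean anyway).

## Pedigree algebra

Inbreeding coefficients follow the Meuwissen–Luo recursion
(`inbreeding_coefficients`); inside the generation loop the F of a planned
progeny is computed as half the sire–dam relationship, read from sire
columns of A obtained with the matrix-free (indirect) method — two O(n)
pedigree sweeps per distinct sire through the factorisation A = T D T'. The
two routes agree to machine precision (asserted in the tests against the
dense tabular oracle). Relationship matrices are only ever materialised for
subsets (`relationship_matrix`); group means of pairwise relationships
exclude the diagonal, since they describe between-animal relatedness.
A⁻¹ is assembled sparsely by Henderson's rules with inbreeding. The
per-generation inbreeding rate is ΔF = (F_t − F_{t−1})/(1 − F_{t−1}).

## Breeding-value estimation

Each round the mixed-model equations (overall mean as the only fixed
effect; one equation per animal, recorded or not) are rebuilt from the full
pedigree and all phenotypes recorded so far and solved from scratch.
Animals without records and without recorded descendants come out at their
parent-average EBV. An optional record window (`blup_window`) restricts
records to the last g generations for speed; it is off by default.

Solvers: `solve_ebv` uses a direct sparse LU factorisation up to 2×10⁵
equations and Jacobi-preconditioned conjugate gradients (relative-residual
tolerance 1e-8) above. The engine's generation loop defaults to the PCG
path warm-started from the previous round's solution (new animals start at
their parent average): EBVs change little between consecutive rounds, so the
warm start converges in a few dozen iterations and cuts replicate runtime
about sevenfold, while a direct-vs-PCG comparison at desk scale produced
identical selection decisions and trajectories (and the two solvers agree to
1e-6 in the tests). Both paths are deterministic given the inputs.

## The polled locus

Allele counts n_P ∈ {0,1,2}; polled is dominant. Transmission after
generation 0 is one uniformly drawn allele per parent, independent across
progeny; mutation, crossover and linkage to the quantitative trait are not
modelled, and there is no explicit scurs locus.

**Founder assignment** engineers the generation-0 starting state rather than
simulating the history that produced it. Exactly round(2N·0.03) carriers are
created among the N cohort members, all heterozygous (no PP founders).
A share `male_share` = 0.05 of the carriers are male, sampled evenly from
`n_donor_families` = 3 paternal half-sib families restricted to the
below-median TBV stratum (`stratum_quantile` = 0.5); the remaining carriers
are females drawn at random from the below-median half of the cohort
females. Concentrating male carriers in a few low-merit families is the
minimal mechanism that yields both the depressed breeding values and the
elevated mutual relatedness of the polled-male group; the female pool
reproduces the small female TBV deficit without a relatedness excess. The
defaults mirror the full-scale arithmetic (three donor families of ~75
below-median males ≈ 5 % of 4 500 carriers) and keep the carrier sex
composition scale-invariant.

**Phenotyping error.** Each genetically polled calf is recorded horned with
probability 0.02, independently, once, at birth (error flag set); pp calves
are always recorded horned; errors are one-directional and records are
immutable. The error feeds into PHENO selection (which weights the recorded
phenotype) but not into GENO selection (which weights the true allele
count).

## Selection and culling

Within each sex, the current active animals and the new candidate cohort
are ranked separately by weighted EBV: round((1−repl)·current) incumbents
are retained and the remainder of the target slots filled by the top
candidates (repl = 0.50 for sires, 0.25 for dams). Incumbents compete by
their *current* weighted EBV — there is no age-based culling beyond the
replacement rates. Ties break toward the lower animal id. Weighted EBVs are
used for both admission and culling whenever the sex's strategy is active;
the pre-phase (cohorts −4…−1) always ranks on unweighted EBV.

## Scenarios, replication, scaling

The catalogue maps names to per-sex (strategy, wf) pairs: CONTROL (none),
GENO-ALL/M/F and PHENO-ALL/M/F (wf 0.5 where active), GENO-M-PHENO-F
(wf 0.5/0.5), wf-M-0.1 (GENO 0.1 on males, PHENO 0.5 on females) and
wf-M-0.5 (alias of GENO-M-PHENO-F). Each replicate draws from an
independent RNG stream spawned from the scenario's base seed with the
replicate index as spawn key, so any replicate is individually reproducible
and two scenarios with the same base seed share founder randomness (paired
comparisons).

`scale_factor` divides all population sizes (nearest integer, at least two
sires) while replacement *proportions* are preserved, so selection
intensity is approximately scale-invariant. Desk-scale work in the tests
and the acceptance script uses scale 25 (10 sires / 3 000 dams, ~93 000
animals per replicate, a few seconds per replicate).

## What desk-scale runs do and do not reproduce

Scale-invariant to good approximation: the engineered generation-0 state
(exact allele frequency, group contrasts), early selection response, the
qualitative-trait dynamics of the GENO scenarios (endpoint frequencies,
fixation generation), the reduced-weight compromise of wf-M-0.1, and the
ordering of scenarios by endpoint allele frequency.

Not scale-invariant: the rate of inbreeding, which grows roughly with the
inverse of effective population size. At scale 25 the realised ΔF is a few
percent per generation (endpoint mean F ≈ 0.6) versus a few tenths of a
percent at full scale. Two downstream quantities inherit this distortion:
(1) endpoint genetic gain — the (1−F) shrinkage of Mendelian-sampling
variance erodes late response, so desk-scale CONTROL ends near 5.8
phenotypic SD rather than the full-scale ≈ 8.2; (2) the plateau of the
PHENO trajectories — inbreeding converts heterozygotes into homozygotes,
the weighting then culls the pp homozygotes, and the P frequency creeps
above the full-scale ≈ 0.80 plateau (≈ 0.93–0.95 at scale 25). Drift can
also carry the carrier group of a single CONTROL replicate upward instead
of purging it. The corresponding endpoint checks in the acceptance test
suite are kept at their full-scale tolerances and fail honestly at desk
scale; inbreeding comparisons across scenarios are therefore directional
only (GENO-on-males scenarios end below CONTROL in mean F at equal scale,
which does hold).

The simulator also idealises real breeding programs: discrete rounds
without explicit age structure, no herd/year fixed effects, variances known
to the evaluation (no REML), no genomic information, and a single error
rate standing in for the scurs locus. Passing tests therefore demonstrate
internal consistency of the model and its algebra, not predictions for any
particular real population.

## Degenerate inputs and numerical edges

Founders must have both parents unknown; mixed known/unknown parent pairs,
out-of-order parents and wrong-sex parents are structural errors. A record
set that is empty leaves the mean equation singular: the assembled system
is flagged degenerate and refuses to solve. ΔF is undefined at F_prev = 1.
Fully inbred parents give exactly mid-parent progeny TBV. Weighting factors
must be non-negative; `target_freq` must lie in [0, 0.5] (all-heterozygous
carriers cannot exceed frequency one half).
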