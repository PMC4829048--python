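# Methods

## Scope

`pedpop` estimates the size of a wildlife population from noninvasively
collected SNP genotypes by (i) matching degraded per-sample calls into
unique individuals, (ii) reconstructing the sampled pedigree by likelihood
parentage assignment, (iii) applying a pedigree-based estimator
(N̂ = N_s + N_in + N_un) and a rarefaction estimator, and (iv) evaluating
both with an individual-based demographic simulator that provides ground
truth. The design target is the noninvasive brown-bear setting: a 96-assay
panel (85 autosomal SNPs, 4 mtDNA species assays, 4 Y and 3 X sex assays),
fecal DNA with allelic dropout and per-call typing error, overlapping
generations, polygynandrous mating and female philopatry.

## Marker panel and genotype model

Autosomal genotypes are biallelic, encoded as the dosage of a reference
allele (0/1/2, −1 missing). The mt/Y/X assays are presence calls used only
for species confirmation and sexing:

- bear: ≥ 3 of 4 mt assays called;
- male: ≥ 3 of 4 Y assays called;
- female: 0 Y calls and ≥ 2 of 3 X calls.

The rules are deliberately one-sided: 1–2 Y calls return UNKNOWN rather
than male, and a sample can never be called female in the presence of any
Y call, so a poorly amplified male is refused rather than feminized.
Samples with ≤ 70 called assays (of 96; configurable, strict inequality)
are discarded before matching.

## Individual identification

QC-passed, species-confirmed samples are clustered by single linkage: two
samples link iff they share ≥ 40 co-called autosomal loci and disagree at
≤ 2 of them. With 85 SNPs, distinct bears differ at dozens of loci while
two samples of one animal differ only through typing error, so the two
thresholds are far apart; both are exposed in the configuration because
the right values depend on the realized error rate. Consensus genotypes
are per-locus majority calls with ties set to missing — never resolved
arbitrarily. Sex-assay calls are pooled across member samples (a call in
any member counts); clusters whose member samples carry conflicting
per-sample sex calls are flagged, not silently merged. Each individual's
location is the componentwise median of its sample locations, which is
robust to the occasional far-flung sample.

## Lynch–Ritland relatedness

For reference x = (a,b) and proband y = (c,d) at a locus with allele
frequencies p_a, p_b:

    num = p_a (S_bc + S_bd) + p_b (S_ac + S_ad) − 4 p_a p_b
    den = (1 + S_ab)(p_a + p_b) − 4 p_a p_b

The multilocus estimate is Σnum/Σden (weighted form) and the reported r
averages the two directions. The weighted form is not optional for SNPs: a
heterozygous reference at p = 0.5 has den = 0, so per-locus averaging
would divide by zero. Allele frequencies are plug-in estimates from the
*individual* consensus genotypes, not from samples, to avoid weighting by
resampling frequency; an external frequency table can be supplied. Pairs
with < 20 informative loci are flagged low-confidence. Monte-Carlo
calibration on the 85-SNP panel: unrelated 0.00, parent–offspring and
full sibs 0.50, half sibs 0.25 (verified in the test suite).

## Parentage engine

Pedigree reconstruction is per-offspring maximum likelihood with a
posterior-odds gate — a deterministic, desk-scale replacement for an MCMC
pedigree sampler, chosen because only the triad/dyad/unassigned table and
the breeder set feed the estimator.

*Error model.* An observed call is correct with probability 1 − ε,
otherwise uniform over the other two calls. ε defaults to 0.01; a
low-error preset of 1.538 × 10⁻⁴ matches high-quality extracts. The
likelihood marginalizes the error in **all** observed genotypes: each
parent's true genotype gets a posterior from its observed call under a
Hardy–Weinberg prior. Treating parental calls as exact would let a single
parental miscall at a forced-transmission locus (e.g. AA × AA → observed
AB offspring) veto a true trio; with marginalization the same event costs
a bounded penalty.

*Screening and scoring.* Candidate parents must have ≤ ⌈2εL⌉ opposing
homozygote loci with the focal individual (L = co-called loci). Each focal
individual's configurations — best trio, best dam-only dyad, best
sire-only dyad, or no sampled parent — are scored by likelihood ratio
against the both-parents-unsampled null plus a prior: with ceilings
Nf_max/Nm_max on the candidate populations (defaults: twice the sampled
count of each sex), the prior that a specific sampled female is the dam is
1/Nf_max and that the dam is unsampled is 1 − n_F/Nf_max. The best
configuration is accepted iff its posterior odds exceed 10 (configurable).

*Global consistency.* Without ages, the direction of an isolated
parent–offspring dyad is unidentifiable — the dyad likelihood ratio is
exactly symmetric. Mutual claims (A names B as parent and B names A) are
resolved structurally: within a 10-log-unit odds window, the individual
claimed as a parent by more focal individuals wins (a dam with several
sampled offspring is claimed by all of them; an offspring is claimed by
one animal). Outside the window the stronger claim wins. Remaining
assignments are applied greedily in decreasing odds with cycle rejection,
so the result is always acyclic and sex-consistent. Near-ties between
distinct candidates are broken lexicographically and flagged ambiguous.
An age hook exists (`use_age`) but is off by default since noninvasive
studies rarely know ages; single-child parent pairs therefore retain an
irreducible direction ambiguity, visible as a small precision/recall gap
(≈ 0.97/0.94 at full sampling with ε = 0.01, vs 1.0/1.0 at ε = 0).

## Population estimators

*Pedigree-based estimate.* From the reconstructed pedigree: N_s
individuals, B_s breeders, the dyad list, and ρ = distinct dams / distinct
sires. The full-sibling screen links dyad-offspring of the same known
parent with r ≥ `fs_threshold` (default 0.375, the midpoint between the
half-sib and full-sib expectations); each linked component of ≥ 2
offspring yields exactly one inferred missing parent. Remaining dyads are
converted by the ratio rule x = round(D_d/ρ), y = round(S_d·ρ), which
preserves ρ after inference and reduces to the identity at ρ = 1. If a
pedigree contains no known dams or no known sires, ρ carries no
information and defaults to 1. Mortality correction applies one year of
sex-specific adult mortality to the inferred parents, **rounding per sex
before summation** — the only rounding order consistent with both
published worked examples (58/69 → 115 and 45/48 → 85; pooled rounding
gives 84 for the latter). The unsampled-non-breeder term N_un has no
published closed form; three strategies are selectable, with
`nonbreeder_fraction` (apply the sampled non-breeder fraction to the
inferred individuals) as the default because it is interpretable and lands
nearest the published totals. No confidence interval is defined for this
estimator; the reported bounds are [N_s, N_s + dyads at zero mortality].

*Rarefaction.* y = ax/(b+x) is fitted to the genotype accumulation curve
by bounded least squares, initialized at a₀ = max(y), b₀ = median(x), with
parameter tolerance 10⁻⁸ and an iteration cap of 500. Constant curves are
degenerate; fits whose asymptote exceeds 50× the observed maximum are in
the unsaturated regime where a and b are jointly unidentifiable and are
flagged unconverged (a sample set with every individual seen once is the
extreme case). 100 random sample orderings are fitted and the converged
asymptotes averaged. This model is known to overestimate at high sampling
effort — which is useful, since the pedigree estimator errs low at modest
coverage; the two bracket the truth.

## Synthetic populations

The simulator generates what the analysis assumes, with ground truth:

- Founders under Hardy–Weinberg at panel frequencies (drawn uniform on
  (0.1, 0.9)); ages from the stationary distribution of the mortality
  schedule; centers uniform on a 100 × 100 planar study area.
- Annual cycle: every breeding-age (≥ 5 yr) female draws a litter
  (Poisson, mean `litter_size_mean`, truncated at 4) and a sire weighted
  by exp(−d²/2σ²) proximity (σ = 30), so sires repeat across females —
  the multi-dam sires the ratio method needs. Offspring are Mendelian;
  daughters settle at philopatry SD 5, sons at dispersal SD 20. One
  mortality Bernoulli per individual per year: `cub_mortality` below
  breeding age, else 7.2 % (F) / 11.6 % (M).
- Defaults `litter_size_mean = 0.8` cubs/female/yr (≈ a litter of 2.4
  every 3 years) and `cub_mortality = 0.29` put the Euler–Lotka growth
  factor at ≈ 1.0 under those adult rates, so populations are roughly
  stationary over the simulated decade.
- Sampling: per-individual sample counts are zero-inflated Poisson
  (π = 0.35, λ = 2.0), giving ≈ 55–60 % of the population sampled at
  ≈ 1.3 samples per animal — the coverage regime of the motivating
  surveys. Sample locations are uniform on a disk (radius 5) around the
  individual's center. Calls suffer independent per-locus dropout
  (default 0.05) and per-call typing error (default 0.01; an erroneous
  call becomes one of the other two calls uniformly). The mt/Y/X presence
  assays are subject to dropout only: the sexing rules are designed
  against dropout, and the assay chemistry has no analogue of a false
  positive presence call in this error model. Y assays never amplify in
  females.

What the simulator does **not** emulate: landscape/habitat structure,
harvest dynamics, age-dependent fecundity, genotyping batch effects,
cross-contaminated samples, or non-target species. Passing tests
demonstrate the statistical machinery under the stated assumptions, not
robustness to those field realities.

All stochastic stages draw from generators seeded deterministically from a
single master seed; repeated runs are byte-identical.

## Evaluation experiments

- *Sampling-intensity sweep*: draw round(level × N_ref) individuals
  without replacement, rerun reconstruction + estimation, 10 replicates
  per level; report CV = sd/mean and the percentage difference
  100·|N_ref − mean|/mean (denominator = the estimate, the reading under
  which a deficit at low intensity can exceed 100 %). Precision and
  accuracy improve with intensity; below ~40 % the estimator severely
  underestimates because few dyads are recoverable — this holds even with
  the true pedigree supplied, i.e. it is a property of the estimator, not
  of reconstruction error.
- *Edge effects*: subsets of n individuals nearest the median center and
  nearest each border of the bounding rectangle of the individual centers
  (geographic boundaries are out of scope); pedigree completeness per
  subset is compared by Pearson's χ² homogeneity test. Sex-separated
  subsets contrast mother–daughter vs father–son dyads; under female
  philopatry the mother–daughter counts dominate in border subsets.
- Supporting statistics: percentage relative precision
  (100 · CI half-width / estimate), the pooled two-proportion z-test, and
  the one-sample t-test for verifying mean r against 0.5. The pooled z
  for the published breeder proportions (159/433 vs 112/265) evaluates to
  −1.46; the study prints −1.42, whose exact variant is not documented —
  this package reports the standard pooled statistic.

## Numerical and degenerate-input policy

Likelihood tables are floored at 10⁻³⁰⁰ before logs inside the
reconstruction engine (the public `trio_loglik`/`single_parent_loglik`
return true −∞ at ε = 0 exclusions). Monomorphic loci get frequencies
clipped to 10⁻⁶, which gives them ~zero weight in the relatedness
estimator instead of NaNs. Empty location lists, single-individual
rarefaction inputs, non-positive ratios, out-of-range probabilities and
candidate pools above the configured ceilings raise or warn explicitly.
Consensus ties, equal-likelihood parentage candidates and edge subsets
that exhaust the population are flagged rather than silently resolved.

## Problem sizes used in validation

The test suite exercises populations of ~60–150 founders over 10–12 years
(≈ 175–450 individuals ever alive, ≈ 50–150 alive at sampling), 85-locus
genotypes, 250–500 Monte-Carlo pairs for relatedness calibration, and
sweeps of 6 replicates at 2 levels — sizes at which every statistical
property under test is comfortably resolved while the whole suite runs in
well under a minute of compute per module.

## Known limitations

- Direction of single-child parent–offspring dyads is unidentifiable
  without ages; the engine's structural resolution removes most but not
  all flips.
- Full siblings of an individual whose true parents are unsampled can be
  accepted as stand-in parents at elevated error rates (their likelihood
  penalty is a handful of opposing-homozygote loci); the posterior-odds
  gate bounds but does not eliminate this.
- The N_un term is a modelling choice, not an estimate with sampling
  theory behind it; the strategy is configurable and the bounds do not
  depend on it.
- The rarefaction model's high-effort overestimation is inherited by
  design; alternative accumulation models are out of scope.
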