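# pedpop

Population-size estimation from reconstructed pedigrees, for noninvasive
SNP genotyping studies of wildlife.

Counting wild animals that are rare, solitary and wide-ranging — brown
bears are the motivating case — is usually done by genetic
capture–mark–recapture on fecal samples. A reconstructed pedigree contains
strictly more information than the recapture histories alone: an offspring
whose dam is genotyped but whose sire is not reveals the existence of an
*unsampled* individual. `pedpop` implements the full chain from raw
per-sample SNP calls to a pedigree-based population estimate, together
with a rarefaction estimator, an individual-based population simulator for
validation, and the supporting evaluation experiments.

## The estimators

**Pedigree-based (Creel–Rosenblatt) estimator.** With N_s genotyped
individuals, B_s known breeders (≥ 1 offspring in the pedigree) and
one-parent dyads in the reconstructed pedigree,

    N̂ = N_s + N_in + N_un

- `N_in` counts the parents missing from the dyads, without inferring one
  new animal per dyad: offspring of the same known parent whose pairwise
  Lynch–Ritland relatedness indicates full siblings (r ≥ 0.375 by
  default) share a single inferred parent; the remaining dyads are scaled
  by the pedigree's dam:sire ratio ρ (x = round(D_d/ρ) missing sires from
  D_d distinct known dams, y = round(S_d·ρ) missing dams), so ρ is
  preserved after inference. One year of sex-specific adult mortality
  (7.2 %/yr dams, 11.6 %/yr sires, rounded per sex) discounts inferred
  parents that may already be dead.
- `N_un` estimates individuals that neither bred nor were sampled; by
  default the sampled non-breeder fraction is applied to the inferred
  individuals, N_un = round(N_in · (N_s − B_s)/N_s) (configurable).
- Bounds: lower = N_s; upper treats every dyad as one new individual with
  zero mortality.

The pedigree itself is reconstructed by a deterministic
maximum-likelihood parentage engine: Mendelian-exclusion screening of
candidate parents (allowing ⌈2εL⌉ mismatches at per-call error rate ε),
trio/dyad likelihoods with the genotyping-error model marginalized over
all three genotypes, a posterior-odds gate against the
"both parents unsampled" null, and a global acyclicity resolution.

**Rarefaction (accumulation-curve) estimator.** The cumulative number of
unique genotypes y against samples drawn x is fitted with the saturation
model y = ax/(b + x); the asymptote `a` estimates population size. The
fit is repeated over 100 random sample orderings and the asymptotes
averaged.

**Lynch–Ritland relatedness** (weighted ratio-of-sums across loci,
reciprocally averaged) verifies reconstructed parent–offspring pairs
(expectation 0.5) and drives the full-sibling screen.

## Worked example

Simulate a bear-like population, sample it noninvasively, and estimate its
size (all data synthetic; no downloads):

```python
from pedpop import (SimConfig, simulate_population, collect_samples,
                    identify_individuals, allele_frequencies, lr_matrix,
                    ParentageModel, ParentageConfig,
                    CreelRosenblattModel, RarefactionModel)

cfg = SimConfig(seed=7, n_founders=150, n_years=12)
pop = simulate_population(cfg)                 # 153 animals alive
samples = collect_samples(pop, cfg)            # 171 fecal samples
table = identify_individuals(samples)          # 83 unique genotypes
freqs = allele_frequencies(table.genotypes)
ped = ParentageModel(table, freqs).fit(ParentageConfig(typing_error=0.01))
cre = CreelRosenblattModel(ped, lr_matrix(table, freqs)).fit()
print(cre.summary())
```

```
Pedigree-based population estimate
============================================
Sampled genotypes (N_s)                   83
Known breeders (B_s)                      28
Parent-offspring dyads                    30
Dam:sire ratio (rho)                    1.00
Full-sib inferred sires/dams           2 / 1
Ratio-method inferred sires/dams       8 / 11
Inferred after mortality (N_in)           20
Unsampled non-breeders (N_un)             13   [nonbreeder_fraction]
Population estimate (N_hat)              116
Bounds [N_s, dyads no-mortality]    [83, 133]
Increase over genotype count             40%
```

The 83 genotypes cover 54 % of the 153 animals actually alive. The
pedigree estimate of 116 recovers a substantial part of the unsampled
population but still undershoots — expected behaviour below ~60 %
sampling intensity. The rarefaction estimate on the same samples,

```python
member = {s: i for i, ms in zip(table.ids, table.members) for s in ms}
seq = [member[s.sample_id] for s in samples.samples if s.sample_id in member]
print(RarefactionModel(seq).fit(n_iter=100, seed=1).summary())
```

gives a mean asymptote of 161.4 — a slight overestimate, as this model
tends to produce at high sampling effort. Bracketing the truth between
the two estimators is exactly how they are meant to be used together.

The same chain is available from the shell:

```bash
pedpop simulate --seed 7 --founders 150 --years 12 --out samples.csv
pedpop identify --samples samples.csv --out individuals.csv
pedpop pedigree --individuals individuals.csv --eps 0.01 --out pedigree.csv
pedpop estimate cre --pedigree pedigree.csv --individuals individuals.csv --out cre.json
pedpop run --config config.yaml        # full pipeline + JSON report
```

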