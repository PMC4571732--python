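# Methods

## Model structure and assumptions

`itnevo` couples a mechanistic description of the mosquito feeding
cycle to a one-locus, two-allele, two-sex selection model. The core
assumptions are:

- A single autosomal locus controls resistance; dominance *h* acts
  identically on the resistance benefit (larval and adult survival) and
  on its cost *Z*.
- Generations are discrete and non-overlapping; mating is random, so
  zygote genotype proportions are cross-products of the parental male
  and female allele frequencies. No mutation, migration, density
  dependence or overlapping generations.
- Larvicide coverage ψ kills all sensitive larvae in treated sites;
  survival is standardized to 1 in untreated sites, so only relative
  larval fitness matters.
- Males never contact ITNs; their only resistance effects are larval
  survival and the fertility cost.
- Female adult survival comes from the feeding cycle: each attempt
  targets an animal (1−Q) or a human indoors (Q), with probability ϕ of
  hitting an ITN-protected house; the insecticide repels with
  probability r, otherwise kills with genotype-dependent probability
  1−s_g. Repeated searches after repulsion incur extra mortality μ_r
  and do not lengthen the gonotrophic cycle. Mosquito behaviour (Q, r)
  does not itself evolve, and outdoor human feeding is not modelled.

The fitness of a genotype is its lifetime reproductive output: for
females, larval survival × fecundity κ × cost factor × expected number
of gonotrophic cycles survived; for males, larval survival × cost
factor. Fitnesses are stored as absolute values (κ included) even
though every recursion step divides by mean fitness, so κ has no effect
on the dynamics; keeping it makes the female entries interpretable as
offspring numbers.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| ϕ (`phi`) | ITN coverage | 0 (per scenario) | probability |
| ψ (`psi`) | larvicide coverage | 0 (per scenario) | probability |
| Q | indoor human-feeding probability | 0.7 | probability |
| r | repellency of treated nets | 0.7 | probability |
| s | sensitive survival of insecticide exposure | 0.16 | probability |
| σ (`sigma`) | survival of feeding-associated risk | 0.9 | probability |
| μ (`mu`) | daily adult mortality | 0.1 | /day |
| gt | gonotrophic cycle length | 3 | days |
| μ_gt (`mu_gt`) | per-cycle mortality override | derived | probability |
| μ_r (`mu_r`) | extra mortality per repeat search | 0.03 | probability |
| h | dominance of resistance | 0.25 | – |
| ρ (`rho`) | resistance level | 0.95 | – |
| Z | fecundity/fertility cost of resistance | 0.10 | – |
| κ (`kappa`) | female fecundity | 100 | offspring |

Defaults are the typical values reported in field-study reviews for
African malaria vectors. μ_gt is derived exactly as 1−(1−μ)^gt
(= 0.271 at the defaults); published tabulations often round this to
0.27, and the `mu_gt` override field reproduces such rounded values
when exact replication of a printed table is wanted. Both coverages
default to 0 so that a freshly constructed parameter set describes an
intervention-free population; every scenario sets ϕ and/or ψ
explicitly.

Validation is strict (no clamping): probabilities must lie in [0, 1],
gt and κ must be positive, and Qϕr(1−μ_r) < 1 is enforced at
construction so the repeat-search geometric series always converges.
Clamping would silently mask configuration errors.

## Invasion analysis and thresholds

A rare allele occurs almost only in heterozygotes, so linearizing the
recursion at a monomorphic resident gives the growth factor
λ = ½(W_m,RS/W_m,res + W_f,RS/W_f,res); λ > 1 means the allele
increases when rare. Coverage thresholds are defined through these
analytic factors — `invasion`: λ_R > 1; `fixation`: λ_R > 1 and
λ_S < 1 — and located by a 101-point grid pre-scan followed by
predicate bisection to absolute tolerance 1e-4. Bisection on the
boolean criterion (rather than root-finding on λ−1) was chosen because
the fixation criterion is a conjunction of inequalities, not a single
continuous function. If the criterion changes state more than once
along the grid, the smallest crossing is returned and a warning is
logged. A coverage at which the resident genotype itself has zero
fitness (e.g. ψ = 1 against sensitive residents) is treated as an
infinite growth factor inside the threshold scan; the public
`invasion_growth_factor` raises `ResidentInviableError` there instead
of inventing a number.

For larvicide-only selection at the defaults there is a narrow band,
ψ ∈ (0.0974, 0.1074), in which both λ_R > 1 and λ_S > 1: each allele
invades when rare and the trajectory settles at an interior equilibrium
(a protected polymorphism). `classify_outcome` reports `not-converged`
there rather than forcing a fixation/elimination label.

## Dynamics, tolerances and conventions

- Trajectories iterate the recursion with scalar arithmetic; fixation
  is declared when the sex-averaged frequency exceeds 1 − 1e-6,
  elimination when it falls below 1e-9. The elimination cut sits well
  below the customary initial frequency of 1e-5, so a declining allele
  is never misread as eliminated prematurely. Default generation cap:
  50 000.
- "Time to 50%" and all outcome tests are evaluated on the sex-averaged
  frequency (p_m + p_f)/2, the quantity the neutral recursion preserves
  exactly; the per-sex frequencies differ transiently because male and
  female fitnesses differ.
- Reported percentage thresholds are rounded half-up to whole percent,
  matching the granularity at which such coverages are usually quoted.
- Degenerate corners fail loudly: zero mean fitness raises
  `PopulationExtinctError`; an undefined ITN/larvicide time ratio
  (larvicide scenario never reaching the target) raises
  `UndefinedRatioError`, while an ITN-only scenario that never gets
  there yields an infinite ratio. In CSV output these serialize as the
  strings `"undefined"`, `"inf"` and `"never"`, never as sentinel
  numbers.

## Finite-population sampling model

The Wright–Fisher-style oracle embeds the recursion in a population of
constant census sizes N_m, N_f (soft selection). The state is the
post-selection adult genotype counts per sex. Each generation, the
adults' allele frequencies define random-mating zygote proportions;
weighting by the sex-specific fitnesses gives each sex's post-selection
genotype distribution, and the new adult counts are one multinomial
draw per sex. Drawing the two sexes from their own post-selection
distributions (rather than both from a common zygote pool) is what
makes the expectation of each sex's allele frequency follow the
deterministic recursion exactly; sampling both sexes from the shared
zygote distribution would re-average p_m and p_f every generation and
introduce a systematic bias of order (p_m − p_f)² that is visible even
at N = 10^6. Runs are reproducible bit-for-bit under a fixed seed
(numpy `default_rng`).

## Synthetic scenarios and what the tests show

The model needs no external data: all experiments are parameter sweeps
from the default set, with initial allele frequency 1e-5 in both sexes
(a freshly arisen but established allele, as in the published
scenarios). The sweep grids default to 101 points on [0, 1] for
coverage axes, with curve families over r, Q and ψ following the ranges
used in the original figures; tests use coarser grids (3–11 points)
purely to keep the suite fast, and the monotonicity checks use
0.1/0.2-step grids. Because the engine is deterministic and closed-form,
these reduced grids probe the same mathematics as the full ones.

Passing tests establish the internal consistency of the model —
closed forms against series expansions, linearizations against the full
recursion, sampling against the deterministic limit, thresholds against
brute-force scans — and reproduce its qualitative field-scale
predictions (larvicides select much faster than ITNs; repellency and
zoophily delay resistance). They do not validate the parameter values
against any particular mosquito population, nor the behavioural
assumptions (no outdoor feeding, non-evolving behaviour, equal
resistance expression in larvae and adults) on which the quantitative
predictions rest.

## Known limitations

- No mutation or migration: an allele below the elimination tolerance
  is gone forever, so establishment probabilities of new mutants are
  out of scope (the stochastic module is an oracle, not a drift-theory
  tool).
- Hard larvicide kill (sensitive larvae in treated sites always die)
  and a single insecticide class; no dose-response, no synergists, no
  mosaic or rotation strategies.
- The feeding-cycle approximation holds when repeated host searches are
  short relative to the gonotrophic cycle; at coverage and repellency
  both near 1 this assumption weakens.
- Fitness costs act on fecundity/fertility only, not on longevity.
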