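# Methods

This note documents the models and procedures implemented in `reefcs`, the
defaults they use, the synthetic scenario they are exercised on, and the
numerical and design choices that were genuinely open.

## Monitoring design and the synthetic scenario

The generator reproduces the structure of a volunteer reef-monitoring
programme in the Indo-Pacific: 6 sites x 3 habitat zones (reef flat, crest,
upper slope) x 3 replicate permanent transects, with one site lacking a
reef flat — 51 permanent transects — surveyed annually over 2002–2012.
Campaign missingness is year-specific: fractions 0.49, 0.33 and 0.22 of the
transect roster are unsampled in 2004, 2006 and 2007, and 0.06 in
2002/2003/2008/2009, yielding ≈ 496 sampled transect-years. Which transects
are missed is uniform at random within a year; the exchangeable mechanism
is the simplest one consistent with per-year missing fractions, and no
site/habitat clustering of missingness is modelled.

**Benthic cover.** Six categories (hard coral, soft coral, macroalgae,
rock, rubble, sand; initial means 45.8/15.6/16.4/9.2/7.0/6.0%). The
per-year hard-coral mean follows a declining trajectory from 45.8% to
14.0%, with its largest year-on-year drops (10.3 and 8.5 percentage
points) between 2004→2005 and 2007→2008. Coral lost relative to the first
year moves into the abiotic categories proportionally to their initial
shares; soft-coral and macroalgal means are held at their initial values.
This emulates the coral→rubble/rock replacement that degrading reefs show;
it does not emulate transient macroalgal blooms (a mid-study algal rise and
fall is one feature of real series the generator omits). Transect noise is
additive Gaussian per category (SD 5 percentage points) on the simplex,
clipped at zero and renormalised to sum exactly 100.

**Fish counts.** A 33-species pool spanning 13 families. Counts are
zero-inflated negative binomial: with probability π a structural zero,
otherwise NB with mean `exp(β0_s + β1_s·coral + u_t)` and dispersion θ,
where `u_t ~ N(0, σ²)` is one draw per year shared by all transects — the
same grouping the fitted models assume. Defaults: |β1| = 0.05 per % cover,
σ = 0.3, θ = 2, π = 0.2. Four families (Acanthuridae, Nemipteridae,
Pomacanthidae, Epinephelinae — detritivores and invertebrate feeders that
benefit from coral loss) carry β1 = −0.05; the other nine
(coral-dwelling/feeding taxa such as Anthiinae, Pomacentridae,
Chaetodontidae) carry β1 = +0.05. Baseline abundances are set so that
eight families exceed 1% of community abundance. Only records with count
> 0 are emitted, as in diver datasheets.

**Observer error.** Three modes, each logged in a truth ledger: (i)
phantom species — a Poisson(24)-distributed number of in-region species
absent from the true community, each planted in exactly one transect-year
with 1–3 individuals, so each satisfies the singleton-removal predicate by
construction; (ii) out-of-range misidentifications — each record of a
species with a designated extralimital lookalike is relabelled to it with
probability 0.03; (iii) accidental cryptic/transient-pelagic records at
rate 0.05 per transect-year. The rates were chosen once so that the
cleaned fraction of species falls in the regime long-running volunteer
programmes report (roughly a third of species as one-off records carrying
< 1% of abundance, ~20% extralimital, a few percent out-of-design); they
are scenario constants, not tuning knobs. Diver-identity effects, spatial
autocorrelation and within-year dynamics are not modelled.

**SST.** A 12-month climatology for Southeast Sulawesi (peak 29.4 °C) plus
+1.3 °C anomalies in 2002, 2005 and 2006 and N(0, 0.1²) noise; the anomaly
years reliably cross the 30.38 °C bleaching threshold and no other year
does.

**Seeding.** One master seed expands via `numpy.random.SeedSequence` into
per-stage substreams in the fixed order design → benthic → fish → observer
→ sst; this order is part of the reproducibility contract, and identical
seeds give bit-identical tables.

## Quality control

Stages run in the order singleton removal → out-of-range reassignment →
excluded-guild removal. "Single transect" is read as a single
(site, habitat, transect, year) cell: an occurrence unique in space *and*
time, which is what "did not reappear in previous or subsequent years"
implies. Reassignment adds flagged species' counts cell-wise to their
`reassign_to` target (creating target rows where absent) and conserves
total abundance exactly — asserted as integer equality. All report
percentages are referenced to the initial dataset; because it is not
obvious whether such reductions should be quoted on species incidence or on
records/abundance, the report emits both. The three stages are idempotent:
nothing a stage keeps can later satisfy a removal predicate, since kept
species only ever gain occurrence cells. The FishBase range lookup and
photographic similarity matching used in practice are replaced by an
explicit `in_region` flag and `reassign_to` column in the traits checklist,
removing network and image dependencies while preserving the computation.

## Degree Heating Months

Per year, the count of months whose mean SST strictly exceeds the
threshold ("exceeded" read literally, so ties do not count); years with
count ≥ 1 are flagged. Missing months contribute nothing (with a warning);
duplicate (year, month) rows are an error. Counts are monotonically
non-increasing in the threshold and invariant to month order. Raw monthly
means are compared — no climatology adjustment is applied.

## Community change

The community matrix holds, per year, each species' mean count over the
transects sampled that year (absent species count as zero). Denominators
are per-year sampled-transect counts, so unbalanced campaigns are handled
without imputation. Bray–Curtis is computed after an optional abundance
transform (default none — the transform must be stated in any report
header; √ and ⁴√ are available for downweighting dominants). Two all-zero
rows have distance 0 by convention.

**nMDS.** Kruskal-style: each restart alternates (a) isotonic regression
of configuration distances on the dissimilarity order (primary tie
approach, pool-adjacent-violators) giving monotone disparities, and (b) a
Guttman majorization update, with step-halving so the stress-1 trace never
increases; convergence when the improvement drops below 1e-6 (max 500
iterations). Defaults: 2 dimensions, 50 restarts — the first initialised
from classical metric scaling (so exactly embeddable inputs reach stress
≈ 0 immediately), the rest random. Configurations that merge samples whose
dissimilarity is not itself near zero are rejected as degenerate: rank-based
stress can be driven to zero by collapsing samples into a few points, a
known pathology with strongly clustered data. The best configuration is
centred and scaled to unit RMS.

**Seriation (RELATE).** The model matrix is `m(i,j) = |i − j|` over the
rank positions of the years actually present (gap years are not inserted).
ρ is the Spearman (midrank) correlation of the two condensed upper
triangles. Inference relabels samples: exact enumeration of all n!
relabellings when n ≤ 7, otherwise `n_perm` random relabellings (default
999) with the one-sided add-one estimate `p = (1 + #{ρ* ≥ ρ}) / (1 +
n_perm)`. A constant matrix has undefined ρ and is returned as ρ = 0 with a
degenerate flag.

**SIMPROF.** Group-average (UPGMA) clustering on Bray–Curtis. At each node,
the observed profile of ordered dissimilarities is compared with its mean
under datasets in which each species' values are permuted independently
across the node's samples (999 permutations for the mean profile); the
statistic is π = Σ_k |s_(k) − s̄_(k)| and its null distribution comes from a
second, independent 999-permutation set. Recursion descends only through
significant nodes (α = 0.05); leaves of the stopped recursion are the
reported year groups. Nodes whose rows are identical are one homogeneous
group without testing. If the permutation count cannot attain p < α a
warning is raised.

## Count models

NB2 parameterisation throughout (variance μ + μ²/θ), log link, hard-coral
cover entered untransformed in percent units; the zero-inflation component
is intercept-only (no covariates on π). The year random intercept's
marginal likelihood is integrated by *adaptive* Gauss–Hermite quadrature:
per year group, the integrand's mode is found by a vectorised Newton search
and the quadrature grid is centred and scaled by the curvature there
(default 15 nodes; the log-likelihood stabilises well before 25 nodes).
At σ < 1e-4 the integral collapses to the fixed-effects likelihood at
u = 0, which equals an independent fixed-effects-only fit to machine
precision — this limiting identity, and the recovery of the plain NB
likelihood from ZINB at γ0 = −20, are asserted in the test suite against
`statsmodels` oracles.

Optimisation is bounded L-BFGS-B over (β0, β1, σ ∈ [0, 5], log θ ∈ [−7, 7],
γ0 ∈ [−30, 10]) from a moment-based start, with up to 5 jittered restarts
stopping early once two starts agree on the optimum. Wald SEs come from a
central-difference Hessian at the optimum; directions pinned at a bound
(σ at 0 — reported, not suppressed, via a `boundary_sigma` flag) or flat
(γ0 driven below −10, i.e. π < 5e-5, when the data need no structural
zeros) are dropped from the Hessian rather than inverted into nonsense.
AIC = 2k − 2·logLik with k counting all free parameters; selection takes
the converged candidate with minimal AIC, ties resolved toward fewer
parameters. How to choose between Poisson and NB is left open in common
practice; AIC is this package's documented choice, for community abundance
and richness (non-zero-inflated candidates only) as well as for the
ZIP/ZINB family and species fits.

Screening rules: families are tested at 0.05 with no multiple-testing
correction by default (matching common practice in monitoring reports;
a Benjamini–Hochberg step can be layered on the returned p-values);
species-level fits run only inside families that are significant *and*
contribute > 1% of community abundance, and cover the smallest
descending-share prefix of species reaching 90% of family abundance.
Degenerate inputs (all-zero response, constant coral, a single year level)
raise immediately; a family whose fit fails is recorded in the screening
result and does not abort the screen. Site is deliberately not modelled as
a random effect, and there are no random slopes.

## Pipeline

`run_full_pipeline` executes simulate (or load) → QC → DHM → benthic
trends → community battery → models, writes every intermediate as CSV/JSON
and a consolidated JSON + markdown report with a provenance header (config
hash, seed, package version) — supporting the handover use-case where a
volunteer organisation re-runs the analysis unattended. Analysis-stage
seeds are substreams of the master seed, so a config + seed pair yields
byte-identical reports. Benthic trends report per-year means ± SE over
transects (SE set to 0 with a flag for single-transect years) and the
relative hard-coral change (first − last)/first.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to give stable verdicts at
interactive runtimes: seriation null calibration uses 500 datasets of 10
samples with 199 permutations; SIMPROF type-I calibration 200 datasets of
8 exchangeable rows with 199 + 199 permutations (the 999-permutation
default is an accuracy choice for real analyses, not a calibration
requirement); GLMM slope recovery 200 replicates at the generator defaults
on a balanced 45-transect x 11-year roster (495 rows); Wald-p null
calibration 200 replicates of 220 rows. The end-to-end checks run the full
default scenario (~496 transect-years, 33 true species, 13 families).

## Known limitations

- The generator's exchangeable missingness, stable soft-coral/algae means
  and absence of observer-identity effects mean that passing tests
  demonstrate correctness of the statistical machinery under the stated
  model, not robustness to every failure mode of real volunteer data.
- Zero-inflation is intercept-only; structural zeros correlated with coral
  cover would be absorbed into β1.
- The seriation test conditions on the years present; long gaps compress
  the time model.
- nMDS stress near zero with strongly clustered data can reflect the
  rank criterion's weakness rather than a meaningful embedding; the
  degeneracy guard rejects outright collapse but clustered configurations
  with low stress remain faithful to the criterion.
- SIMPROF's sequential testing is conservative; its empirical type-I rate
  sits below the nominal α, which the calibration band acknowledges.
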