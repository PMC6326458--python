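# reefcs

Analysis pipeline for long-term, volunteer-collected coral-reef monitoring
data: quality control of citizen-science fish surveys, thermal-stress
detection from sea-surface temperature, permutation-based tests of
multivariate community change, and zero-inflated count mixed models linking
fish abundance to hard-coral cover.

It is aimed at reef-monitoring programmes (and the scientists who hand them
over to local stakeholders) that survey permanent transects annually with
volunteer divers: fixed sites x habitat zones (reef flat, crest, slope) x
replicate transects, percent benthic cover by Line Intercept Transect, and
single-diver underwater visual fish censuses.

## What it computes

**Quality control.** Volunteer fish records pass through three treatment
stages: (1) species whose every record falls in a single transect of a
single year are removed as likely one-off misidentifications; (2) species
never recorded in the study region are flagged and their abundances added,
cell-wise, to a designated in-region lookalike of the same family (total
abundance is conserved exactly); (3) accidental records of cryptic and
transient-pelagic species, which the survey design does not target, are
dropped. The report gives species, record and abundance percentages per
stage, all relative to the initial dataset.

**Degree Heating Months.** A DHM is a month whose mean SST strictly exceeds
the regional bleaching threshold (default 30.38 °C, the Coral Reef Watch
value for Southeast Sulawesi); years with ≥ 1 DHM are flagged.

**Community change.** Annual mean abundance per species
→ Bray–Curtis dissimilarity `d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j)`
(optional √ or ⁴√ transform) → (a) non-metric MDS minimising Kruskal
stress-1 `√(Σ(d̂_ij − δ̂_ij)² / Σ d̂_ij²)` by majorization with isotonic
regression; (b) a seriation (RELATE-type) test: Spearman matrix correlation
ρ between the dissimilarities and the ideal time-ordered model
`m(i,j) = |i − j|`, with permutation (or exact enumeration) inference;
(c) a SIMPROF test on a group-average dendrogram delimiting statistically
significant year groups at α = 0.05.

**Coral–fish models.** Random-intercept count GLMMs on the log link,

    log μ_it = β0 + β1·coral_it + u_t,   u_t ~ N(0, σ²),

Poisson / NB2 (variance μ + μ²/θ) and their zero-inflated variants with an
intercept-only structural-zero logit (π = expit(γ0)), fitted by adaptive
Gauss–Hermite quadrature with AIC selection. Community abundance and
richness use Poisson/NB; fish families use ZIP/ZINB, and families whose
coral slope is significant at 0.05 *and* whose abundance exceeds 1% of the
community total get species-level fits for the most abundant species
covering ≥ 90% of the family's abundance.

**Synthetic data.** Because raw monitoring data are rarely shareable, the
package ships a generator that emulates the full design — 51 permanent
transects (6 sites x 3 zones x 3 replicates, one site without a reef flat),
11 annual campaigns with year-specific missingness, a declining hard-coral
trajectory compensated by abiotic cover, zero-inflated NB fish counts with
species-specific coral slopes and a shared year intercept, volunteer
observer errors with a truth ledger, and monthly SST with warm anomalies.
Every analysis is therefore testable end-to-end from a single seed.

## Worked example

```python
import reefcs as rc

data = rc.simulate_dataset(seed=7)                      # full campaign
clean, report = rc.run_qc(data["fish_observed"], data["traits"])
print(report.to_text())

dhm = rc.compute_dhm(data["sst"])                       # threshold 30.38 °C
print("DHM years:", dhm.flagged_years)

d = rc.bray_curtis(rc.annual_mean_matrix(clean))
print(rc.relate_seriation(d, seed=2).to_dict())
```

prints

```
Volunteer-data quality control report
initial: 76 species, 9844 records, 86822 individuals
  singleton_removal: 25 species (32.9%), 25 records (0.25%), 63 individuals (0.07%)
  out_of_range_reassignment: 14 species (18.4%), 160 records (1.63%), 2049 individuals (2.36%)
  excluded_guild_removal: 4 species (5.3%), 18 records (0.18%), 29 individuals (0.03%)
DHM years: [2002, 2005, 2006]
{'rho': 0.8699597745842894, 'p': 0.001, 'n_perm': 999, 'exact': False, 'degenerate': False}
```

i.e. about a third of recorded species were one-off records carrying < 0.1%
of total abundance, three years crossed the bleaching threshold, and the
fish community shows a strongly significant sequential year-on-year drift
(ρ = 0.87, permutation p = 0.001).

The same analysis runs from the shell:

```bash
reefcs simulate --seed 7 --out data/
reefcs qc --fish data/fish.csv --traits data/traits.csv --out clean.csv --report qc.json
reefcs dhm --sst data/sst.csv --threshold 30.38
reefcs run --config config.yaml        # full pipeline with one seed
```

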