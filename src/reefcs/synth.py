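"""Synthetic survey-data generator for a volunteer reef-monitoring programme.

Emulates the sampling design and error structure the downstream analyses
assume: a nested transect design (sites x {flat, crest, slope} x replicates,
one site lacking a reef flat), eleven annual campaigns with year-specific
missingness, a declining hard-coral trajectory whose loss is absorbed by the
abiotic categories, zero-inflated negative-binomial fish counts whose
log-mean depends on hard-coral cover with species-specific slopes and a
shared year-level random intercept, volunteer observer error (spurious
singleton species, out-of-range misidentifications, accidental
cryptic/pelagic records), and monthly sea-surface temperatures with warm
anomalies crossing the regional bleaching threshold.

All generation is driven by a single master seed expanded into per-stage
substreams in the fixed order: design, benthic, fish, observer, sst.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HABITATS = ("flat", "crest", "slope")
BENTHIC_CATEGORIES = ("hard_coral", "soft_coral", "macroalgae", "rock", "rubble", "sand")
ABIOTIC_CATEGORIES = ("rock", "rubble", "sand")

FISH_COLUMNS = ["site", "habitat", "transect", "year", "species", "count"]
CELL_COLUMNS = ["site", "habitat", "transect", "year"]

# Stream order of the master-seed expansion; part of the reproducibility
# contract relied on by the pipeline.
STREAM_ORDER = ("design", "benthic", "fish", "observer", "sst")


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    """Expand one master seed into named, independent per-stage generators."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_ORDER))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAM_ORDER, children)}


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Geometry of the nested monitoring design.

    ``flat_absent_sites`` lists sites where the reef-flat zone does not
    exist; their flat transects are never established. Missing fractions
    give, per year, the fraction of permanent transects not sampled in
    that campaign.
    """

    sites: tuple[str, ...]
    habitats: tuple[str, ...] = HABITATS
    replicates_per_zone: int = 3
    flat_absent_sites: frozenset[str] = frozenset()
    years: tuple[int, ...] = ()
    missing_fraction_by_year: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sites:
            raise ValueError("design requires at least one site")
        if not self.years:
            raise ValueError("design requires at least one year")
        if self.replicates_per_zone < 1:
            raise ValueError("replicates_per_zone must be >= 1")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if not set(self.flat_absent_sites) <= set(self.sites):
            raise ValueError("flat_absent_sites must be a subset of sites")
        for y, f in self.missing_fraction_by_year.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"missing fraction for {y} must be in [0, 1)")

    @property
    def n_permanent_transects(self) -> int:
        full = len(self.sites) * len(self.habitats) * self.replicates_per_zone
        return full - len(self.flat_absent_sites) * self.replicates_per_zone

    def permanent_transects(self) -> pd.DataFrame:
        rows = []
        for site, habitat in itertools.product(self.sites, self.habitats):
            if habitat == "flat" and site in self.flat_absent_sites:
                continue
            for r in range(1, self.replicates_per_zone + 1):
                rows.append((site, habitat, f"{site}-{habitat}-{r}"))
        return pd.DataFrame(rows, columns=["site", "habitat", "transect"])


def default_design() -> StudyDesign:
    """The monitoring scenario: 6 sites, 3 zones x 3 replicates with one
    flat-less site (51 permanent transects), 2002-2012, and heavy campaign
    missingness in 2004/2006/2007 (~496 sampled transect-years)."""
    return StudyDesign(
        sites=("Pak Kasim", "Ridge", "KDS", "Kaledupa", "Buoy 3", "Sampela"),
        habitats=HABITATS,
        replicates_per_zone=3,
        flat_absent_sites=frozenset({"Ridge"}),
        years=tuple(range(2002, 2013)),
        missing_fraction_by_year={
            2002: 0.06, 2003: 0.06, 2004: 0.49, 2006: 0.33,
            2007: 0.22, 2008: 0.06, 2009: 0.06,
        },
    )


def generate_design(design: StudyDesign, seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the transect roster: one row per permanent transect x year with
    a ``sampled`` flag.

    Per year a uniformly random subset of size round((1 - f) * N) is marked
    sampled, f being that year's missing fraction. Deterministic given seed.
    """
    rng = _as_rng(seed)
    permanent = design.permanent_transects()
    n = len(permanent)
    frames = []
    for year in design.years:
        f = design.missing_fraction_by_year.get(year, 0.0)
        n_sampled = int(round((1.0 - f) * n))
        sampled_idx = rng.choice(n, size=n_sampled, replace=False)
        block = permanent.copy()
        block["year"] = year
        block["sampled"] = False
        block.loc[block.index[sampled_idx], "sampled"] = True
        frames.append(block)
    roster = pd.concat(frames, ignore_index=True)
    return roster[["site", "habitat", "transect", "year", "sampled"]]


# ---------------------------------------------------------------------------
# Benthic cover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenthicParams:
    """Mean benthic composition and its trajectory.

    ``coral_trajectory`` gives the target mean hard-coral % per year; the
    cover lost relative to the first year is absorbed by the abiotic
    categories (rock, rubble, sand) in proportion to their initial shares,
    while soft coral and macroalgae keep their initial means. Transect-level
    noise is additive Gaussian on each category, clipped at zero and
    renormalised to 100.
    """

    initial_cover: dict[str, float]
    coral_trajectory: dict[int, float]
    cover_noise_sd: float = 5.0

    def __post_init__(self):
        if set(self.initial_cover) != set(BENTHIC_CATEGORIES):
            raise ValueError(f"initial_cover must define exactly {BENTHIC_CATEGORIES}")
        if any(v < 0 for v in self.initial_cover.values()):
            raise ValueError("initial covers must be non-negative")
        if abs(sum(self.initial_cover.values()) - 100.0) > 1e-9:
            raise ValueError("initial covers must sum to 100")
        if any(not (0.0 <= v <= 100.0) for v in self.coral_trajectory.values()):
            raise ValueError("trajectory values must be in [0, 100]")
        if self.cover_noise_sd < 0:
            raise ValueError("cover_noise_sd must be >= 0")


def default_benthic_params() -> BenthicParams:
    # Trajectory interpolates the reported endpoints 45.8 -> 14.0 with the
    # two largest year-on-year drops (10.3 and 8.5 percentage points) placed
    # at 2004->2005 and 2007->2008.
    trajectory = {
        2002: 45.8, 2003: 44.0, 2004: 42.5, 2005: 32.2, 2006: 30.0,
        2007: 28.0, 2008: 19.5, 2009: 18.0, 2010: 16.5, 2011: 15.0,
        2012: 14.0,
    }
    initial = {
        "hard_coral": 45.8, "soft_coral": 15.6, "macroalgae": 16.4,
        "rock": 9.2, "rubble": 7.0, "sand": 6.0,
    }
    return BenthicParams(initial_cover=initial, coral_trajectory=trajectory)


def simulate_benthic(
    roster: pd.DataFrame,
    params: BenthicParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per sampled transect-year, draw six covers >= 0 summing to exactly 100."""
    rng = _as_rng(seed)
    sampled = roster[roster["sampled"]].reset_index(drop=True)
    years = sampled["year"].unique()
    missing = [int(y) for y in years if y not in params.coral_trajectory]
    if missing:
        raise ValueError(f"coral_trajectory missing years: {missing}")

    coral0 = params.initial_cover["hard_coral"]
    abiotic0 = np.array([params.initial_cover[c] for c in ABIOTIC_CATEGORIES])
    abiotic_share = abiotic0 / abiotic0.sum()

    mean_by_year = {}
    for y in years:
        coral_y = params.coral_trajectory[y]
        means = dict(params.initial_cover)
        means["hard_coral"] = coral_y
        # coral loss (or gain) relative to the first-year mean moves into
        # the abiotic categories proportionally to their initial shares
        shift = coral0 - coral_y
        for cat, share in zip(ABIOTIC_CATEGORIES, abiotic_share):
            means[cat] = params.initial_cover[cat] + shift * share
        mean_by_year[y] = np.array([means[c] for c in BENTHIC_CATEGORIES])

    mu = np.stack([mean_by_year[y] for y in sampled["year"]])
    if params.cover_noise_sd > 0:
        covers = mu + rng.normal(0.0, params.cover_noise_sd, size=mu.shape)
        covers = np.clip(covers, 0.0, None)
        covers = 100.0 * covers / covers.sum(axis=1, keepdims=True)
    else:
        covers = mu
    out = sampled[CELL_COLUMNS].copy()
    for j, cat in enumerate(BENTHIC_CATEGORIES):
        out[cat] = covers[:, j]
    return out


# ---------------------------------------------------------------------------
# Fish community
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """Generative parameters of one species.

    ``beta0`` is the log baseline abundance per transect at 0% coral,
    ``beta1`` the log-linear hard-coral slope (per % cover), ``pi`` the
    structural-zero probability and ``theta`` the negative-binomial
    dispersion (variance mu + mu^2/theta).
    """

    name: str
    family: str
    beta0: float
    beta1: float
    pi: float = 0.2
    theta: float = 2.0

    def __post_init__(self):
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must be in [0, 1)")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass(frozen=True)
class FishCommunityParams:
    species: tuple[SpeciesParams, ...]
    year_sd: float = 0.3

    def __post_init__(self):
        if self.year_sd < 0:
            raise ValueError("year_sd must be >= 0")
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")


def _sp(name, family, mean_at_30, beta1, **kw) -> SpeciesParams:
    # parameterised by the expected count at 30% coral for readability
    return SpeciesParams(name=name, family=family,
                         beta0=float(np.log(mean_at_30) - beta1 * 30.0),
                         beta1=beta1, **kw)


#: 13 families with hard-coral slopes of the sign reported for each: four
#: benefit from coral loss (negative coral slope), nine decline with it.
DEFAULT_SPECIES_POOL: tuple[SpeciesParams, ...] = (
    # negative coral slope (abundance rises as coral declines)
    _sp("Ctenochaetus striatus", "Acanthuridae", 10.0, -0.05),
    _sp("Acanthurus nigrofuscus", "Acanthuridae", 6.0, -0.05),
    _sp("Zebrasoma scopas", "Acanthuridae", 3.0, -0.05),
    _sp("Scolopsis bilineata", "Nemipteridae", 3.0, -0.05),
    _sp("Scolopsis margaritifera", "Nemipteridae", 2.0, -0.05),
    _sp("Centropyge vrolikii", "Pomacanthidae", 2.5, -0.05),
    _sp("Centropyge bicolor", "Pomacanthidae", 1.5, -0.05),
    _sp("Cephalopholis cyanostigma", "Epinephelinae", 0.5, -0.05),
    _sp("Cephalopholis boenak", "Epinephelinae", 0.3, -0.05),
    # positive coral slope (abundance declines with coral loss)
    _sp("Pseudanthias squamipinnis", "Anthiinae", 30.0, 0.05),
    _sp("Pseudanthias huchtii", "Anthiinae", 12.0, 0.05),
    _sp("Pseudanthias dispar", "Anthiinae", 6.0, 0.05),
    _sp("Balistapus undulatus", "Balistidae", 0.6, 0.05),
    _sp("Sufflamen chrysopterum", "Balistidae", 0.4, 0.05),
    _sp("Forcipiger flavissimus", "Chaetodontidae", 5.0, 0.05),
    _sp("Chaetodon kleinii", "Chaetodontidae", 3.0, 0.05),
    _sp("Chaetodon trifascialis", "Chaetodontidae", 2.0, 0.05),
    _sp("Sargocentron caudimaculatum", "Holocentridae", 1.0, 0.05),
    _sp("Myripristis violacea", "Holocentridae", 0.7, 0.05),
    _sp("Thalassoma lunare", "Labridae", 8.0, 0.05),
    _sp("Halichoeres hortulanus", "Labridae", 5.0, 0.05),
    _sp("Labroides dimidiatus", "Labridae", 3.0, 0.05),
    _sp("Cirrhilabrus cyanopleura", "Labridae", 2.0, 0.05),
    _sp("Lutjanus decussatus", "Lutjanidae", 1.0, 0.05),
    _sp("Macolor niger", "Lutjanidae", 0.6, 0.05),
    _sp("Chromis margaritifer", "Pomacentridae", 25.0, 0.05),
    _sp("Pomacentrus moluccensis", "Pomacentridae", 15.0, 0.05),
    _sp("Dascyllus trimaculatus", "Pomacentridae", 10.0, 0.05),
    _sp("Chrysiptera rollandi", "Pomacentridae", 6.0, 0.05),
    _sp("Amblyglyphidodon curacao", "Pomacentridae", 4.0, 0.05),
    _sp("Pseudochromis paccagnellae", "Pseudochromidae", 4.0, 0.05),
    _sp("Pseudochromis fuscus", "Pseudochromidae", 2.0, 0.05),
    _sp("Zanclus cornutus", "Zanclidae", 0.6, 0.05),
)


def default_fish_params() -> FishCommunityParams:
    return FishCommunityParams(species=DEFAULT_SPECIES_POOL, year_sd=0.3)


def simulate_fish_counts(
    roster: pd.DataFrame,
    benthic: pd.DataFrame,
    params: FishCommunityParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw zero-inflated NB counts per sampled transect-year and species.

    Count for species s in transect i, year t: with probability pi_s a
    structural zero, otherwise NB with mean exp(beta0_s + beta1_s * coral_it
    + u_t) and dispersion theta_s, where u_t ~ N(0, year_sd^2) is shared by
    all transects of year t. Only rows with count > 0 are emitted, matching
    what divers record.
    """
    rng = _as_rng(seed)
    sampled = roster[roster["sampled"]]
    cells = sampled.merge(benthic[CELL_COLUMNS + ["hard_coral"]], on=CELL_COLUMNS, how="left")
    if cells["hard_coral"].isna().any():
        bad = cells[cells["hard_coral"].isna()][CELL_COLUMNS].iloc[0].tolist()
        raise ValueError(f"benthic row missing for sampled transect-year {bad}")

    years = np.sort(cells["year"].unique())
    u = dict(zip(years, rng.normal(0.0, params.year_sd, size=len(years))))
    u_row = cells["year"].map(u).to_numpy()
    coral = cells["hard_coral"].to_numpy()
    n_rows = len(cells)

    frames = []
    for sp in params.species:
        mu = np.exp(sp.beta0 + sp.beta1 * coral + u_row)
        # gamma-poisson mixture == NB(mean mu, size theta)
        lam = rng.gamma(sp.theta, mu / sp.theta)
        counts = rng.poisson(lam)
        structural = rng.random(n_rows) < sp.pi
        counts[structural] = 0
        keep = counts > 0
        if keep.any():
            block = cells.loc[keep, CELL_COLUMNS].copy()
            block["species"] = sp.name
            block["count"] = counts[keep]
            frames.append(block)
    fish = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FISH_COLUMNS)
    return fish[FISH_COLUMNS].sort_values(FISH_COLUMNS[:5]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Species traits checklist
# ---------------------------------------------------------------------------

#: lookalike -> (family, in-region species whose records it absorbs in error)
DEFAULT_LOOKALIKES: dict[str, tuple[str, str]] = {
    "Acanthurus leucosternon": ("Acanthuridae", "Acanthurus nigrofuscus"),
    "Ctenochaetus truncatus": ("Acanthuridae", "Ctenochaetus striatus"),
    "Pseudanthias ventralis": ("Anthiinae", "Pseudanthias dispar"),
    "Pseudanthias bicolor": ("Anthiinae", "Pseudanthias huchtii"),
    "Chaetodon larvatus": ("Chaetodontidae", "Chaetodon kleinii"),
    "Chaetodon fremblii": ("Chaetodontidae", "Chaetodon trifascialis"),
    "Thalassoma duperrey": ("Labridae", "Thalassoma lunare"),
    "Halichoeres ornatissimus": ("Labridae", "Halichoeres hortulanus"),
    "Labroides phthirophagus": ("Labridae", "Labroides dimidiatus"),
    "Chromis ovalis": ("Pomacentridae", "Chromis margaritifer"),
    "Pomacentrus alleni": ("Pomacentridae", "Pomacentrus moluccensis"),
    "Dascyllus albisella": ("Pomacentridae", "Dascyllus trimaculatus"),
    "Chrysiptera galba": ("Pomacentridae", "Chrysiptera rollandi"),
    "Pseudochromis flavivertex": ("Pseudochromidae", "Pseudochromis paccagnellae"),
}

#: species outside the programme design accidentally recorded by volunteers
DEFAULT_EXCLUDED_GUILD_SPECIES: dict[str, tuple[str, str]] = {
    "Pseudocheilinus hexataenia": ("Labridae", "cryptic"),
    "Ecsenius bicolor": ("Blenniidae", "cryptic"),
    "Caranx melampygus": ("Carangidae", "transient_pelagic"),
    "Sphyraena barracuda": ("Sphyraenidae", "transient_pelagic"),
}

#: pool of plausible one-off phantom identifications (in-region, standard
#: guild, simply absent from the true community)
DEFAULT_PHANTOM_POOL: tuple[tuple[str, str], ...] = tuple(
    (f"Phantomspecies {chr(97 + i // 26)}{chr(97 + i % 26)}", fam)
    for i, fam in enumerate(
        ["Acanthuridae", "Anthiinae", "Balistidae", "Chaetodontidae",
         "Epinephelinae", "Holocentridae", "Labridae", "Lutjanidae",
         "Nemipteridae", "Pomacanthidae", "Pomacentridae", "Pseudochromidae",
         "Zanclidae"] * 3 + ["Labridae"]
    )
)


def default_traits(params: FishCommunityParams | None = None) -> pd.DataFrame:
    """Checklist covering true species, lookalikes, phantoms and excluded
    guilds: columns species, family, in_region, guild, reassign_to."""
    params = params or default_fish_params()
    rows = [(s.name, s.family, True, "standard", "") for s in params.species]
    rows += [(name, fam, False, "standard", target)
             for name, (fam, target) in DEFAULT_LOOKALIKES.items()]
    rows += [(name, fam, True, guild, "")
             for name, (fam, guild) in DEFAULT_EXCLUDED_GUILD_SPECIES.items()]
    rows += [(name, fam, True, "standard", "") for name, fam in DEFAULT_PHANTOM_POOL]
    return pd.DataFrame(rows, columns=["species", "family", "in_region", "guild", "reassign_to"])


# ---------------------------------------------------------------------------
# Observer error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverErrorParams:
    """Rates of the three volunteer error modes the QC stage removes.

    spurious_species_rate: expected number of phantom species per dataset,
    each confined to a single transect-year with 1-3 individuals.
    misid_rate: per-record probability that a record of a species with a
    known out-of-range lookalike is relabelled to that lookalike.
    cryptic_record_rate: per sampled transect-year probability of an
    accidental cryptic/pelagic record.
    """

    spurious_species_rate: float = 24.0
    misid_rate: float = 0.03
    cryptic_record_rate: float = 0.05

    def __post_init__(self):
        if self.spurious_species_rate < 0:
            raise ValueError("spurious_species_rate must be >= 0")
        for p in (self.misid_rate, self.cryptic_record_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("rates that are probabilities must be in [0, 1]")


def inject_observer_error(
    fish: pd.DataFrame,
    traits: pd.DataFrame,
    params: ObserverErrorParams,
    seed: int | np.random.Generator | None = None,
    roster: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Corrupt a true fish table with volunteer errors; return it with a
    truth ledger of every corruption (so QC recall/precision is computable).

    Pools are derived from the traits checklist: phantoms are in-region
    standard-guild species absent from the true table, lookalikes are the
    out-of-range species (each relabelling records of its ``reassign_to``
    source), and cryptic/pelagic accidents come from the excluded guilds.
    """
    rng = _as_rng(seed)
    fish = fish.copy()
    true_species = set(fish["species"])
    ledger: dict = {"phantoms": [], "misids": [], "cryptics": []}

    if roster is not None:
        cells = roster.loc[roster["sampled"], CELL_COLUMNS]
    else:
        cells = fish[CELL_COLUMNS].drop_duplicates()
    cells = cells.reset_index(drop=True)

    # --- out-of-range misidentifications -----------------------------------
    if params.misid_rate > 0:
        oor = traits[~traits["in_region"]]
        if oor.empty:
            raise ValueError("misid_rate > 0 but traits contain no out-of-range lookalikes")
        source_to_lookalike = {r.reassign_to: r.species for r in oor.itertuples()}
        eligible = fish["species"].isin(source_to_lookalike).to_numpy()
        hit = eligible & (rng.random(len(fish)) < params.misid_rate)
        for idx in np.flatnonzero(hit):
            row = fish.iloc[idx]
            lookalike = source_to_lookalike[row["species"]]
            ledger["misids"].append({
                "original_species": row["species"], "lookalike": lookalike,
                "site": row["site"], "habitat": row["habitat"],
                "transect": row["transect"], "year": int(row["year"]),
                "count": int(row["count"]),
            })
            fish.iloc[idx, fish.columns.get_loc("species")] = lookalike
        # merge duplicate (cell, species) rows a relabel may have created
        fish = fish.groupby(FISH_COLUMNS[:5], as_index=False)["count"].sum()

    # --- spurious singleton species ----------------------------------------
    n_phantom = rng.poisson(params.spurious_species_rate)
    if n_phantom > 0:
        pool = traits[traits["in_region"] & (traits["guild"] == "standard")
                      & ~traits["species"].isin(true_species)]["species"].tolist()
        if n_phantom > len(pool):
            raise ValueError("phantom pool in traits too small for spurious_species_rate")
        chosen = rng.choice(pool, size=n_phantom, replace=False)
        cell_idx = rng.integers(0, len(cells), size=n_phantom)
        extra = []
        for name, ci in zip(chosen, cell_idx):
            cell = cells.iloc[ci]
            count = int(rng.integers(1, 4))
            extra.append((cell["site"], cell["habitat"], cell["transect"],
                          int(cell["year"]), name, count))
            ledger["phantoms"].append({
                "species": name, "site": cell["site"], "habitat": cell["habitat"],
                "transect": cell["transect"], "year": int(cell["year"]), "count": count,
            })
        fish = pd.concat([fish, pd.DataFrame(extra, columns=FISH_COLUMNS)], ignore_index=True)

    # --- accidental cryptic / transient-pelagic records ---------------------
    if params.cryptic_record_rate > 0:
        cryptic_pool = traits[traits["guild"].isin(["cryptic", "transient_pelagic"])]["species"].tolist()
        if cryptic_pool:
            hit = rng.random(len(cells)) < params.cryptic_record_rate
            extra = []
            for ci in np.flatnonzero(hit):
                cell = cells.iloc[ci]
                name = str(rng.choice(cryptic_pool))
                count = int(rng.integers(1, 3))
                extra.append((cell["site"], cell["habitat"], cell["transect"],
                              int(cell["year"]), name, count))
                ledger["cryptics"].append({
                    "species": name, "site": cell["site"], "habitat": cell["habitat"],
                    "transect": cell["transect"], "year": int(cell["year"]), "count": count,
                })
            if extra:
                fish = pd.concat([fish, pd.DataFrame(extra, columns=FISH_COLUMNS)],
                                 ignore_index=True)
                fish = fish.groupby(FISH_COLUMNS[:5], as_index=False)["count"].sum()

    fish = fish[FISH_COLUMNS].sort_values(FISH_COLUMNS[:5]).reset_index(drop=True)
    return fish, ledger


# ---------------------------------------------------------------------------
# Sea-surface temperature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSTParams:
    """Monthly SST model: a 12-month climatology plus year-specific warm
    anomalies and Gaussian noise, compared downstream against the regional
    bleaching threshold (default 30.38 degC)."""

    climatology: tuple[float, ...]
    anomaly_years: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    threshold: float = 30.38

    def __post_init__(self):
        if len(self.climatology) != 12:
            raise ValueError("climatology must have 12 monthly values")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_sst_params() -> SSTParams:
    # Southeast Sulawesi-like climatology (warm Nov-May, peak ~29.4 degC);
    # +1.3 degC anomalies in the three reported thermal-stress years push
    # the warm-season months over the 30.38 degC bleaching threshold.
    climatology = (28.8, 28.9, 29.2, 29.4, 29.3, 28.9, 28.4, 28.1, 28.2, 28.6, 29.0, 29.3)
    return SSTParams(
        climatology=climatology,
        anomaly_years={2002: 1.3, 2005: 1.3, 2006: 1.3},
        noise_sd=0.1,
        threshold=30.38,
    )


def simulate_sst(
    years,
    params: SSTParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Monthly SST table (year, month, sst_c), 12 rows per year."""
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    rng = _as_rng(seed)
    rows = []
    for y in years:
        anomaly = params.anomaly_years.get(y, 0.0)
        for m in range(1, 13):
            rows.append((int(y), m, params.climatology[m - 1] + anomaly))
    sst = pd.DataFrame(rows, columns=["year", "month", "sst_c"])
    if params.noise_sd > 0:
        sst["sst_c"] = sst["sst_c"] + rng.normal(0.0, params.noise_sd, size=len(sst))
    return sst


# ---------------------------------------------------------------------------
# One-call scenario generation
# ---------------------------------------------------------------------------

def simulate_dataset(
    seed: int,
    design: StudyDesign | None = None,
    benthic_params: BenthicParams | None = None,
    fish_params: FishCommunityParams | None = None,
    observer_params: ObserverErrorParams | None = None,
    sst_params: SSTParams | None = None,
) -> dict:
    """Generate the full study scenario from one master seed.

    Returns a dict with keys roster, benthic, fish_true, fish_observed,
    traits, ledger, sst. Substreams are drawn in the documented order so
    each stage is reproducible independently of the others' parameters.
    """
    design = design or default_design()
    benthic_params = benthic_params or default_benthic_params()
    fish_params = fish_params or default_fish_params()
    observer_params = observer_params if observer_params is not None else ObserverErrorParams()
    sst_params = sst_params or default_sst_params()

    streams = spawn_streams(seed)
    roster = generate_design(design, streams["design"])
    benthic = simulate_benthic(roster, benthic_params, streams["benthic"])
    fish_true = simulate_fish_counts(roster, benthic, fish_params, streams["fish"])
    traits = default_traits(fish_params)
    fish_observed, ledger = inject_observer_error(
        fish_true, traits, observer_params, streams["observer"], roster=roster)
    sst = simulate_sst(design.years, sst_params, streams["sst"])
    return {
        "roster": roster, "benthic": benthic, "fish_true": fish_true,
        "fish_observed": fish_observed, "traits": traits, "ledger": ledger,
        "sst": sst,
    }
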