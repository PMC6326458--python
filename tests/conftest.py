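import numpy as np
import pandas as pd
import pytest

import reefcs as rc


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic monitoring campaign at the default scenario."""
    return rc.simulate_dataset(11)


@pytest.fixture(scope="session")
def clean_fish(default_dataset):
    clean, report = rc.run_qc(default_dataset["fish_observed"], default_dataset["traits"])
    return clean, report


@pytest.fixture(scope="session")
def community_fits_default(default_dataset, clean_fish):
    clean, _ = clean_fish
    return rc.community_models(clean, default_dataset["benthic"], n_restarts=2, seed=0)


@pytest.fixture(scope="session")
def screening_default(default_dataset, clean_fish):
    clean, _ = clean_fish
    return rc.screen_families(clean, default_dataset["benthic"],
                              default_dataset["traits"], n_restarts=2, seed=1)


def _rows(species, cells_counts):
    return [(site, hab, f"{site}-{hab}-{t}", year, species, c)
            for (site, hab, t, year), c in cells_counts]


@pytest.fixture(scope="session")
def qc_fixture():
    """12-species table with hand-computed treatment outcomes.

    Four constructed single-cell species (S1-S4, total abundance 11), two
    out-of-range species (OOR1 -> Target1, OOR2 -> Target2, 12 individuals
    moved over 4 records), one cryptic and one transient-pelagic species
    (10 individuals over 4 records), and four untouched standard species.
    Initial totals: 12 species, 21 records, 82 individuals.
    """
    A, B, C, D = ("SiteA", "crest", 1, 0), ("SiteB", "flat", 1, 0), \
                 ("SiteC", "slope", 1, 0), ("SiteD", "crest", 2, 0)

    def cell(base, year):
        return (base[0], base[1], base[2], year)

    rows = []
    rows += _rows("Singleton1", [(cell(A, 2002), 3)])
    rows += _rows("Singleton2", [(cell(B, 2003), 1)])
    rows += _rows("Singleton3", [(cell(C, 2004), 5)])
    rows += _rows("Singleton4", [(cell(A, 2005), 2)])
    rows += _rows("OOR1", [(cell(A, 2002), 5), (cell(B, 2003), 4)])
    rows += _rows("Target1", [(cell(A, 2002), 2), (cell(D, 2002), 7)])
    rows += _rows("OOR2", [(cell(A, 2002), 1), (cell(C, 2003), 2)])
    rows += _rows("Target2", [(cell(B, 2002), 10), (cell(B, 2003), 4)])
    rows += _rows("CrypticSp", [(cell(A, 2002), 2), (cell(C, 2004), 1)])
    rows += _rows("PelagicSp", [(cell(B, 2002), 6), (cell(D, 2003), 1)])
    rows += _rows("Standard1", [(cell(A, 2002), 8), (cell(B, 2002), 3), (cell(C, 2004), 4)])
    rows += _rows("Standard2", [(cell(D, 2002), 9), (cell(A, 2003), 2)])
    fish = pd.DataFrame(rows, columns=["site", "habitat", "transect", "year", "species", "count"])

    traits = pd.DataFrame([
        ("Singleton1", "FamA", True, "standard", ""),
        ("Singleton2", "FamA", True, "standard", ""),
        ("Singleton3", "FamB", True, "standard", ""),
        ("Singleton4", "FamB", True, "standard", ""),
        ("OOR1", "FamC", False, "standard", "Target1"),
        ("Target1", "FamC", True, "standard", ""),
        ("OOR2", "FamD", False, "standard", "Target2"),
        ("Target2", "FamD", True, "standard", ""),
        ("CrypticSp", "FamE", True, "cryptic", ""),
        ("PelagicSp", "FamF", True, "transient_pelagic", ""),
        ("Standard1", "FamG", True, "standard", ""),
        ("Standard2", "FamG", True, "standard", ""),
    ], columns=["species", "family", "in_region", "guild", "reassign_to"])
    return fish, traits


def zinb_year_data(rng, beta0, beta1=0.05, sigma=0.3, theta=2.0, pi=0.2,
                   n_years=11, per_year=45, coral_range=(14.0, 46.0)):
    """Draw one dataset from the generative count model (shared helper for
    recovery/calibration simulations)."""
    n = n_years * per_year
    year = np.repeat(np.arange(n_years), per_year)
    coral = rng.uniform(*coral_range, n)
    u = rng.normal(0.0, sigma, n_years)
    mu = np.exp(beta0 + beta1 * coral + u[year])
    y = rng.poisson(rng.gamma(theta, mu / theta)) if np.isfinite(theta) else rng.poisson(mu)
    if pi > 0:
        y[rng.random(n) < pi] = 0
    return y, coral, year
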