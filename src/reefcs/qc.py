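"""Three-stage treatment of volunteer fish-survey data.

Stage 1 removes species whose every record falls in a single transect of a
single year (likely one-off misidentifications). Stage 2 flags species never
recorded in the study region and folds their abundances into a designated
in-region lookalike of the same family, conserving total abundance exactly.
Stage 3 drops accidental records of cryptic and transient-pelagic species,
which the survey design does not target. A quantitative report (species and
abundance affected per stage, as percentages of the initial dataset) is
produced alongside the cleaned table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .synth import FISH_COLUMNS, CELL_COLUMNS

EXCLUDED_GUILDS = ("cryptic", "transient_pelagic")


def _check_fish(fish: pd.DataFrame) -> None:
    missing = [c for c in FISH_COLUMNS if c not in fish.columns]
    if missing:
        raise ValueError(f"fish table missing columns: {missing}")
    if (fish["count"] < 0).any():
        raise ValueError("fish counts must be non-negative")
    if fish.duplicated(subset=FISH_COLUMNS[:5]).any():
        raise ValueError("duplicate (site,habitat,transect,year,species) rows")


def _check_traits_cover(fish: pd.DataFrame, traits: pd.DataFrame) -> None:
    unknown = sorted(set(fish["species"]) - set(traits["species"]))
    if unknown:
        raise ValueError(f"species missing from traits checklist: {unknown}")


def remove_singletons(fish: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Remove species confined to exactly one (site, habitat, transect, year)
    cell; return the filtered table and the set of removed species."""
    _check_fish(fish)
    if fish.empty:
        return fish.copy(), set()
    n_cells = (fish.assign(_cell=fish[CELL_COLUMNS].astype(str).agg("|".join, axis=1))
               .groupby("species")["_cell"].nunique())
    removed = set(n_cells.index[n_cells == 1])
    return fish[~fish["species"].isin(removed)].reset_index(drop=True), removed


def flag_out_of_range(fish: pd.DataFrame, traits: pd.DataFrame) -> set[str]:
    """Species recorded but never observed in the study region."""
    _check_fish(fish)
    _check_traits_cover(fish, traits)
    in_region = traits.set_index("species")["in_region"]
    recorded = set(fish["species"])
    return {s for s in recorded if not in_region[s]}


def reassign_flagged(fish: pd.DataFrame, flagged: set[str], traits: pd.DataFrame) -> pd.DataFrame:
    """Fold each flagged species' counts into its designated in-region
    lookalike of the same family, cell-wise; total abundance is conserved."""
    _check_fish(fish)
    if not flagged:
        return fish.copy()
    tr = traits.set_index("species")
    targets = {}
    for s in sorted(flagged):
        target = tr.at[s, "reassign_to"] if s in tr.index else None
        if target is None or (isinstance(target, float) and pd.isna(target)) or target == "":
            raise ValueError(f"flagged species {s!r} has no reassignment target")
        targets[s] = target
    out = fish.copy()
    out["species"] = out["species"].map(lambda s: targets.get(s, s))
    out = out.groupby(FISH_COLUMNS[:5], as_index=False)["count"].sum()
    return out[FISH_COLUMNS].sort_values(FISH_COLUMNS[:5]).reset_index(drop=True)


def remove_excluded_guilds(fish: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Drop all records of cryptic and transient-pelagic species."""
    _check_fish(fish)
    _check_traits_cover(fish, traits)
    guild = traits.set_index("species")["guild"]
    excluded = {s for s in set(fish["species"]) if guild[s] in EXCLUDED_GUILDS}
    return fish[~fish["species"].isin(excluded)].reset_index(drop=True)


@dataclass
class StageResult:
    stage: str
    species_affected: int
    species_pct: float          # % of initial species richness
    records_affected: int
    records_pct: float          # % of initial record rows
    abundance_affected: int     # individuals removed (stages 1, 3) or moved (stage 2)
    abundance_pct: float        # % of initial total abundance
    affected_species: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    """Ordered stage log; all percentages are relative to the initial,
    pre-treatment dataset (species richness, record rows, total abundance).
    Both species-incidence and record/abundance percentages are reported."""

    initial_species: int
    initial_records: int
    initial_abundance: int
    stages: list[StageResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [
            "Volunteer-data quality control report",
            f"initial: {self.initial_species} species, {self.initial_records} records, "
            f"{self.initial_abundance} individuals",
        ]
        for s in self.stages:
            lines.append(
                f"  {s.stage}: {s.species_affected} species ({s.species_pct:.1f}%), "
                f"{s.records_affected} records ({s.records_pct:.2f}%), "
                f"{s.abundance_affected} individuals ({s.abundance_pct:.2f}%)"
            )
        return "\n".join(lines)


def run_qc(fish: pd.DataFrame, traits: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Apply the three treatment stages in order and report their effect.

    Order: singleton removal, then out-of-range flagging + reassignment,
    then excluded-guild removal. Reassignment conserves total abundance, so
    its abundance figure counts individuals moved, not removed.
    """
    _check_fish(fish)
    _check_traits_cover(fish, traits)
    init_species = fish["species"].nunique()
    init_records = len(fish)
    init_abund = int(fish["count"].sum())

    def pct(x, denom):
        return 100.0 * x / denom if denom else 0.0

    report = QCReport(init_species, init_records, init_abund)

    stage1, removed = remove_singletons(fish)
    removed_rows = fish[fish["species"].isin(removed)]
    report.stages.append(StageResult(
        "singleton_removal", len(removed), pct(len(removed), init_species),
        len(removed_rows), pct(len(removed_rows), init_records),
        int(removed_rows["count"].sum()), pct(removed_rows["count"].sum(), init_abund),
        sorted(removed)))

    flagged = flag_out_of_range(stage1, traits)
    flagged_rows = stage1[stage1["species"].isin(flagged)]
    stage2 = reassign_flagged(stage1, flagged, traits)
    assert int(stage2["count"].sum()) == int(stage1["count"].sum())
    report.stages.append(StageResult(
        "out_of_range_reassignment", len(flagged), pct(len(flagged), init_species),
        len(flagged_rows), pct(len(flagged_rows), init_records),
        int(flagged_rows["count"].sum()), pct(flagged_rows["count"].sum(), init_abund),
        sorted(flagged)))

    stage3 = remove_excluded_guilds(stage2, traits)
    guild = traits.set_index("species")["guild"]
    dropped = {s for s in set(stage2["species"]) if guild[s] in EXCLUDED_GUILDS}
    dropped_rows = stage2[stage2["species"].isin(dropped)]
    report.stages.append(StageResult(
        "excluded_guild_removal", len(dropped), pct(len(dropped), init_species),
        len(dropped_rows), pct(len(dropped_rows), init_records),
        int(dropped_rows["count"].sum()), pct(dropped_rows["count"].sum(), init_abund),
        sorted(dropped)))

    return stage3.reset_index(drop=True), report
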