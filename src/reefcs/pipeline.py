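"""End-to-end orchestration: simulate -> QC -> DHM -> community -> models.

One YAML config and one master seed drive the whole analysis; every
intermediate table is written as CSV and a consolidated JSON + markdown
report is produced, with a provenance header (config hash, seed, version)
so a handed-over monitoring programme can re-run and audit the analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import synth
from .community import annual_mean_matrix, bray_curtis, nmds, relate_seriation, simprof
from .glmm import community_models, screen_families
from .qc import run_qc
from .synth import BENTHIC_CATEGORIES
from .thermal import compute_dhm

logger = logging.getLogger("reefcs")


# ---------------------------------------------------------------------------
# Benthic trend summary
# ---------------------------------------------------------------------------

@dataclass
class BenthicTrendSummary:
    """Per-year category means and standard errors over transects, plus the
    relative hard-coral change (first - last) / first."""

    table: pd.DataFrame          # year x (category mean, category se)
    relative_hard_coral_change: float
    single_transect_years: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        flat = self.table.copy()
        flat.columns = [f"{cat}_{stat}" for stat, cat in flat.columns]
        return {
            "relative_hard_coral_change": self.relative_hard_coral_change,
            "single_transect_years": self.single_transect_years,
            "table": flat.reset_index().to_dict(orient="records"),
        }


def benthic_trends(benthic: pd.DataFrame) -> BenthicTrendSummary:
    """Yearly mean +/- SE of each cover category and of the pooled abiotic
    cover (rock + rubble + sand); SE over transects (0 with a flag when a
    year holds a single transect)."""
    if benthic.empty:
        raise ValueError("benthic table is empty")
    df = benthic.copy()
    df["abiotic"] = df[["rock", "rubble", "sand"]].sum(axis=1)
    cats = list(BENTHIC_CATEGORIES) + ["abiotic"]
    g = df.groupby("year")
    means = g[cats].mean()
    ns = g.size()
    sds = g[cats].std(ddof=1)
    ses = sds.div(np.sqrt(ns), axis=0)
    single = sorted(int(y) for y in ns.index[ns == 1])
    ses.loc[single] = 0.0
    table = pd.concat({"mean": means, "se": ses}, axis=1)
    first, last = means.index.min(), means.index.max()
    hc_first = means.at[first, "hard_coral"]
    hc_last = means.at[last, "hard_coral"]
    rel = (hc_first - hc_last) / hc_first if hc_first else float("nan")
    return BenthicTrendSummary(table=table, relative_hard_coral_change=float(rel),
                               single_transect_years=single)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Pipeline settings; either ``generator: true`` (synthesise the inputs)
    or explicit file paths for fish/benthic/traits/sst tables."""

    seed: int
    out_dir: str = "reefcs_out"
    generator: bool = True
    fish_path: str | None = None
    benthic_path: str | None = None
    traits_path: str | None = None
    sst_path: str | None = None
    transform: str = "none"
    alpha: float = 0.05
    n_perm_seriation: int = 999
    n_perm_profile: int = 999
    n_perm_test: int = 999
    nmds_restarts: int = 50
    quad_nodes: int = 15
    glmm_restarts: int = 5
    dhm_threshold_c: float = 30.38

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set a seed (stochastic stages require it)")
        if not self.generator:
            for name in ("fish_path", "benthic_path", "traits_path", "sst_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages require it)")
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, write all intermediates under
    ``config.out_dir`` and return the consolidated report dict.

    Analysis seeds are substreams of the master seed, so reruns with the
    same config are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "reefcs", "version": __version__,
            "seed": config.seed, "config_hash": config.content_hash(),
            "config": asdict(config),
        }
    }

    analysis_ss = np.random.SeedSequence([config.seed, 1])
    s_nmds, s_rel, s_simprof, s_glmm = (np.random.default_rng(s)
                                        for s in analysis_ss.spawn(4))

    if config.generator:
        logger.info("stage simulate: generating synthetic survey data")
        data = synth.simulate_dataset(config.seed)
        fish, benthic, traits, sst = (data["fish_observed"], data["benthic"],
                                      data["traits"], data["sst"])
        (out / "truth_ledger.json").write_text(json.dumps(_jsonable(data["ledger"]), indent=2))
        data["roster"].to_csv(out / "roster.csv", index=False)
    else:
        logger.info("stage load: reading input tables")
        fish = pd.read_csv(config.fish_path)
        benthic = pd.read_csv(config.benthic_path)
        traits = pd.read_csv(config.traits_path, keep_default_na=False)
        sst = pd.read_csv(config.sst_path)
    fish.to_csv(out / "fish_raw.csv", index=False)
    benthic.to_csv(out / "benthic.csv", index=False)
    traits.to_csv(out / "traits.csv", index=False)
    sst.to_csv(out / "sst.csv", index=False)

    logger.info("stage qc: %d records before treatment", len(fish))
    clean, qc_report = run_qc(fish, traits)
    for st in qc_report.stages:
        logger.info("stage qc/%s: removed/moved %d species, %d records",
                    st.stage, st.species_affected, st.records_affected)
    clean.to_csv(out / "fish_clean.csv", index=False)
    (out / "qc_report.json").write_text(qc_report.to_json())
    report["qc"] = qc_report.to_dict()

    logger.info("stage dhm")
    dhm = compute_dhm(sst, config.dhm_threshold_c)
    (out / "dhm.json").write_text(dhm.to_json())
    report["thermal_stress"] = dhm.to_dict()

    logger.info("stage benthic trends")
    trends = benthic_trends(benthic)
    trends.table.to_csv(out / "benthic_trends.csv")
    report["benthic_trends"] = _jsonable(trends.to_dict())

    logger.info("stage community")
    matrix = annual_mean_matrix(clean)
    d = bray_curtis(matrix, transform=config.transform)
    d.to_frame().to_csv(out / "bray_curtis.csv")
    ordination = nmds(d, restarts=config.nmds_restarts, seed=s_nmds)
    ordination.to_frame().to_csv(out / "nmds_coords.csv")
    seriation = relate_seriation(d, n_perm=config.n_perm_seriation, seed=s_rel)
    groups = simprof(matrix, transform=config.transform, alpha=config.alpha,
                     n_perm_profile=config.n_perm_profile,
                     n_perm_test=config.n_perm_test, seed=s_simprof)
    community_report = {
        "transform": config.transform,
        "nmds": {"stress": ordination.stress, "converged": ordination.converged,
                 "best_restart": ordination.best_restart},
        "seriation": seriation.to_dict(),
        "simprof": groups.to_dict(),
    }
    (out / "community.json").write_text(json.dumps(_jsonable(community_report), indent=2))
    report["community"] = community_report

    logger.info("stage glmm: community models")
    comm_fits = community_models(clean, benthic, quad_nodes=config.quad_nodes,
                                 n_restarts=config.glmm_restarts, seed=s_glmm)
    logger.info("stage glmm: family/species screening")
    screening = screen_families(clean, benthic, traits, alpha=config.alpha,
                                quad_nodes=config.quad_nodes,
                                n_restarts=config.glmm_restarts, seed=s_glmm)
    screening.family_table().to_csv(out / "family_screen.csv", index=False)
    screening.species_table().to_csv(out / "species_screen.csv", index=False)
    report["models"] = {
        "community": {k: _jsonable(v.to_dict()) for k, v in comm_fits.items()},
        "families": _jsonable(screening.family_table().to_dict(orient="records")),
        "species": _jsonable(screening.species_table().to_dict(orient="records")),
        "n_significant_families": len(screening.significant_families),
        "selected_families": screening.selected_families,
    }

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    (out / "report.md").write_text(_markdown_report(report))
    logger.info("pipeline complete: %s", out)
    return report


def _markdown_report(report: dict) -> str:
    prov = report["provenance"]
    qc = report["qc"]
    dhm = report["thermal_stress"]
    comm = report["community"]
    models = report["models"]
    trends = report["benthic_trends"]
    lines = [
        "# Reef citizen-science monitoring report",
        "",
        f"- package: {prov['package']} {prov['version']}",
        f"- seed: {prov['seed']}",
        f"- config hash: {prov['config_hash']}",
        f"- abundance transform: {comm['transform']}",
        "",
        "## Data quality control",
        f"Initial dataset: {qc['initial_species']} species, "
        f"{qc['initial_records']} records, {qc['initial_abundance']} individuals.",
        "",
    ]
    for st in qc["stages"]:
        lines.append(f"- {st['stage']}: {st['species_affected']} species "
                     f"({st['species_pct']:.1f}%), abundance {st['abundance_affected']} "
                     f"({st['abundance_pct']:.2f}%)")
    lines += [
        "",
        "## Thermal stress",
        f"Bleaching threshold {dhm['threshold_c']} degC; years with at least one "
        f"Degree Heating Month: {dhm['flagged_years']}.",
        "",
        "## Benthic trend",
        f"Relative hard-coral change over the period: "
        f"{100 * trends['relative_hard_coral_change']:.1f}% decline.",
        "",
        "## Fish community change",
        f"- nMDS stress-1: {comm['nmds']['stress']:.4f}",
        f"- seriation: Rho = {comm['seriation']['rho']:.3f}, p = {comm['seriation']['p']:.4f}",
        f"- SIMPROF year groups: {comm['simprof']['n_groups']} "
        f"({comm['simprof']['groups']})",
        "",
        "## Coral-fish models",
    ]
    for resp, ft in models["community"].items():
        lines.append(f"- community {resp}: {ft['distribution']}, "
                     f"beta1 = {ft['beta1']:.4f} (SE {ft['se_beta1']:.4f}, "
                     f"p = {ft['wald_p']:.3g})")
    lines.append(f"- significant families: {models['n_significant_families']}; "
                 f"species-level screening in {models['selected_families']}")
    return "\n".join(lines) + "\n"
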