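"""File-based pipeline: simulate -> preprocess -> stage1 -> stage2 -> report.

Every stage reads and writes headered CSV plus a JSON metadata sidecar
(config hash, seed, package version), so stages are independently invokable
and composable through files only.  ``run_pipeline`` chains them and, when
ground truth is present (simulated data), emits a planted-vs-estimated
recovery table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger("matlact.pipeline")

import numpy as np
import pandas as pd

from . import __version__
from .pedigree import a_inverse, read_pedigree, write_pedigree
from .preprocess import CircumstanceConfig, apply_filters, assign_circumstance
from .simulate import (SimulationConfig, TRAITS, paper_scale_preset,
                       recovery_preset, simulate_herd, smoke_preset)
from .stage1 import (GibbsConfig, breeding_value_means, build_stage1_model,
                     extract_residuals, fit_animal_model,
                     genetic_merit_percentiles)
from .stage2 import (build_stage2_model, contrast_table, fit_maternal_model,
                     merit_stratified_fit)

PRESETS = {
    "recovery": recovery_preset,
    "smoke": smoke_preset,
    "paper-scale": paper_scale_preset,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "matlact_out"
    preset: str = "recovery"
    sim_overrides: dict = field(default_factory=dict)
    traits: tuple = TRAITS
    factors: tuple = ("lact_group", "yield_group", "mastitis")
    stage1: GibbsConfig = field(default_factory=lambda: GibbsConfig(n_iter=5000, burn_in=500))
    stage2: GibbsConfig = field(default_factory=lambda: GibbsConfig(n_iter=10_000, burn_in=1000))
    merit_fractions: tuple = (0.10, 0.90)
    circumstance: CircumstanceConfig = field(default_factory=CircumstanceConfig)
    seed: int = 20120

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise PipelineError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if dataclasses.is_dataclass(cur) and isinstance(v, dict):
                v = dataclasses.replace(cur, **v)
            elif isinstance(cur, tuple) and isinstance(v, list):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def sim_config(self) -> SimulationConfig:
        if self.preset not in PRESETS:
            raise PipelineError(f"unknown preset {self.preset!r}")
        return PRESETS[self.preset](**{"seed": self.seed, **self.sim_overrides})


def _config_hash(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    return hashlib.sha256(
        json.dumps(obj, default=default, sort_keys=True).encode()
    ).hexdigest()[:16]


def _sidecar(path: Path, config, seed: int, **extra) -> None:
    meta = {
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "version": __version__,
        **extra,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim_config()
    r = simulate_herd(sim_cfg)
    write_pedigree(r.pedigree, out / "pedigree.csv")
    r.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    r.testdays.to_csv(out / "testdays.csv", index=False)
    r.truth.cows.to_csv(out / "truth_cows.csv", index=False)
    (out / "truth_effects.json").write_text(
        json.dumps(
            {
                "planted": r.truth.planted,
                "variance_components": r.truth.variance_components,
                "decile_bounds": r.truth.decile_bounds.tolist(),
            },
            indent=2,
        )
        + "\n"
    )
    for f in ("pedigree.csv", "phenotypes.csv", "testdays.csv", "truth_cows.csv"):
        _sidecar(out / f, sim_cfg, cfg.seed, stage="simulate")


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    ped = read_pedigree(out / "pedigree.csv")
    phen = pd.read_csv(out / "phenotypes.csv", parse_dates=[
        "birth_date", "conception_date", "first_calving_date"])
    td = pd.read_csv(out / "testdays.csv", parse_dates=[
        "calving_date", "dryoff_date", "test_date"])
    kept, excl = apply_filters(phen, td, ped)
    log.info("preprocess: %d records kept, %d excluded", len(kept), len(excl))
    for rule, cnt in excl.groupby("rule").size().items():
        log.info("preprocess: excluded %d by rule %r", cnt, rule)
    circ = assign_circumstance(kept, td, config=cfg.circumstance)
    kept.to_csv(out / "phenotypes_filtered.csv", index=False)
    excl.to_csv(out / "exclusions.csv", index=False)
    circ.to_csv(out / "circumstance.csv", index=False)
    for f in ("phenotypes_filtered.csv", "exclusions.csv", "circumstance.csv"):
        _sidecar(out / f, cfg.circumstance, cfg.seed, stage="preprocess",
                 n_retained=len(kept), n_excluded=len(excl))


def stage_fit1(cfg: PipelineConfig, out: Path) -> None:
    ped = read_pedigree(out / "pedigree.csv")
    kept = pd.read_csv(out / "phenotypes_filtered.csv")
    Ainv = a_inverse(ped)
    res_frames, ebv = [], None
    for trait in cfg.traits:
        model = build_stage1_model(kept, ped, trait, Ainv)
        trait_offset = {"MY": 1, "FP": 2, "DIM": 3}.get(trait, 9)
        chain_cfg = dataclasses.replace(cfg.stage1, seed=cfg.stage1.seed + trait_offset)
        chain = fit_animal_model(model, chain_cfg)
        pd.DataFrame(chain.samples, columns=chain.labels).to_csv(
            out / f"chain1_{trait}.csv", index=False
        )
        _sidecar(out / f"chain1_{trait}.csv", chain_cfg, chain_cfg.seed,
                 stage="stage1", trait=trait)
        res_frames.append(extract_residuals(model, chain))
        if trait == "MY":
            ebv = breeding_value_means(model, chain)
    res = pd.concat(res_frames, ignore_index=True)
    res.to_csv(out / "residuals.csv", index=False)
    _sidecar(out / "residuals.csv", cfg.stage1, cfg.stage1.seed, stage="stage1")
    if ebv is not None:
        ebv.rename("u_hat_MY").to_csv(out / "breeding_values_MY.csv")
        _sidecar(out / "breeding_values_MY.csv", cfg.stage1, cfg.stage1.seed,
                 stage="stage1")


def stage_fit2(cfg: PipelineConfig, out: Path) -> None:
    res = pd.read_csv(out / "residuals.csv")
    circ = pd.read_csv(out / "circumstance.csv")
    tables = []
    for trait in cfg.traits:
        rt = res[res["trait"] == trait]
        for factor in cfg.factors:
            model = build_stage2_model(rt, circ, factor)
            chain = fit_maternal_model(model, cfg.stage2)
            tab = contrast_table(chain)
            tab.insert(0, "trait", trait)
            tables.append(tab)
    report = pd.concat(tables, ignore_index=True)
    report.to_csv(out / "contrasts.csv", index=False)
    _sidecar(out / "contrasts.csv", cfg.stage2, cfg.stage2.seed, stage="stage2")

    # merit-stratified concurrence analysis on milk-yield residuals
    if "MY" in cfg.traits and (out / "breeding_values_MY.csv").exists():
        ebv = pd.read_csv(out / "breeding_values_MY.csv", index_col=0)["u_hat_MY"]
        low, high = genetic_merit_percentiles(ebv, *cfg.merit_fractions)
        strat = merit_stratified_fit(res[res["trait"] == "MY"], circ, (low, high))
        strat.to_csv(out / "merit_stratified.csv", index=False)
        _sidecar(out / "merit_stratified.csv", cfg, cfg.seed, stage="stage2")


def stage_report(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    report = pd.read_csv(out / "contrasts.csv")
    lines = ["# Maternal-circumstance contrast report", ""]
    truth_path = out / "truth_effects.json"
    if truth_path.exists():
        planted = json.loads(truth_path.read_text())["planted"]
        rows = []
        for _, r in report.iterrows():
            f, t, lv = r["factor"], r["trait"], int(r["level"])
            if f == "mastitis":
                true = planted["mastitis"][t] if lv == 1 else 0.0
            else:
                true = planted[f][t][min(lv, len(planted[f][t]) - 1)]
            rows.append(true)
        report["planted"] = rows
        report["abs_error"] = (report["mean"] - report["planted"]).abs()
        lines.append("Planted-vs-estimated contrasts (simulated data):\n")
    lines.append(report.to_string(index=False))
    (out / "report.md").write_text("\n".join(lines) + "\n")
    report.to_csv(out / "report.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# in-memory recovery experiments (the validation harness)
# ---------------------------------------------------------------------------

def _two_stage(result, traits, gibbs1: GibbsConfig, gibbs2: GibbsConfig):
    """Filters -> circumstance -> stage-1 per trait -> residual frames."""
    kept, _ = apply_filters(result.phenotypes, result.testdays, result.pedigree)
    circ = assign_circumstance(kept, result.testdays)
    Ainv = a_inverse(result.pedigree)
    residuals, chains, models = {}, {}, {}
    for k, trait in enumerate(traits):
        model = build_stage1_model(kept, result.pedigree, trait, Ainv)
        chain = fit_animal_model(model, dataclasses.replace(gibbs1, seed=gibbs1.seed + k))
        residuals[trait] = extract_residuals(model, chain)
        chains[trait], models[trait] = chain, model
    return kept, circ, residuals, chains, models


def recovery_lactation_run(seed: int, gibbs1=None, gibbs2=None) -> dict:
    """Recovery preset with the published lactation-group effects planted;
    returns {trait: {level: contrast posterior mean}} for the three traits."""
    gibbs1 = gibbs1 or GibbsConfig(n_iter=5000, burn_in=500, seed=seed + 11)
    gibbs2 = gibbs2 or GibbsConfig(n_iter=5000, burn_in=500, seed=seed + 21)
    r = simulate_herd(recovery_preset(seed=seed))
    _, circ, residuals, _, _ = _two_stage(r, TRAITS, gibbs1, gibbs2)
    out = {}
    for trait in TRAITS:
        chain = fit_maternal_model(
            build_stage2_model(residuals[trait], circ, "lact_group"), gibbs2
        )
        tab = contrast_table(chain)
        out[trait] = dict(zip(tab["level"].astype(int), tab["mean"]))
    return out


def recovery_merit_run(seed: int, gibbs1=None) -> pd.DataFrame:
    """Recovery simulation at heritability 0.3 with a merit x concurrence
    interaction planted for the true top decile; fits the merit-stratified
    concurrence model on the estimated top/bottom deciles."""
    gibbs1 = gibbs1 or GibbsConfig(n_iter=5000, burn_in=500, seed=seed + 31)
    cfg = recovery_preset(
        seed=seed,
        sigma_u={"MY": 65.465, "FP": 0.015, "DIM": 3.0},  # h2 = 0.3 for milk
        maternal_lact={t: (0.0,) * 4 for t in TRAITS},
        merit_interaction={"MY": -90.0, "FP": 0.0, "DIM": 0.0},
    )
    r = simulate_herd(cfg)
    _, circ, residuals, chains, models = _two_stage(
        r, ("MY",), gibbs1, gibbs1
    )
    u_hat = breeding_value_means(models["MY"], chains["MY"])
    low, high = genetic_merit_percentiles(u_hat)
    return merit_stratified_fit(residuals["MY"], circ, (low, high))


def recovery_mastitis_run(seed: int, gibbs1=None, gibbs2=None):
    """Recovery simulation with only the published mastitis effects planted
    (13% exposed dams); returns the lifespan mastitis-vs-healthy contrast."""
    gibbs1 = gibbs1 or GibbsConfig(n_iter=5000, burn_in=500, seed=seed + 41)
    gibbs2 = gibbs2 or GibbsConfig(n_iter=5000, burn_in=500, seed=seed + 51)
    cfg = recovery_preset(
        seed=seed,
        maternal_lact={t: (0.0,) * 4 for t in TRAITS},
        maternal_mastitis={"MY": -18.0, "DIM": -11.0, "FP": 0.0},
    )
    r = simulate_herd(cfg)
    _, circ, residuals, _, _ = _two_stage(r, ("DIM",), gibbs1, gibbs2)
    chain = fit_maternal_model(
        build_stage2_model(residuals["DIM"], circ, "mastitis"), gibbs2
    )
    from .stage2 import contrast

    return contrast(chain, 1)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit-stage1": stage_fit1,
    "fit-stage2": stage_fit2,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Execute all stages in order; returns the final contrast report."""
    out = Path(cfg.out_dir)
    for name in ("simulate", "preprocess", "fit-stage1", "fit-stage2"):
        try:
            STAGES[name](cfg, out)
        except Exception as err:  # noqa: BLE001 - stage-tagged abort
            raise PipelineError(f"stage {name!r} failed: {err}") from err
    return stage_report(cfg, out)
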