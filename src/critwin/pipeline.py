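"""End-to-end orchestration: generate -> expose -> design/fit -> summarize.

Each stage writes delimited-text artifacts into a run directory and can be
re-run from its predecessors' files alone; ``manifest.json`` records the
config hash, seeds, stage timings and row counts so identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import exposure as exposure_mod
from . import summaries as summaries_mod
from . import synthetic
from .sampler import McmcConfig, PosteriorDraws, PriorSpec, run_mcmc

log = logging.getLogger("critwin")

ALL_STAGES = ("generate", "expose", "fit", "summarize")


@dataclass
class RunConfig:
    outdir: str = "critwin_run"
    stages: tuple[str, ...] = ALL_STAGES
    metrics: tuple[str, ...] = ("dense",)
    models: tuple[str, ...] = ("weekly_structured",)
    radius: float = exposure_mod.DEFAULT_RADIUS_KM
    max_week: int = 44
    display_max_week: int | None = None
    write_panel: bool = False
    make_plots: bool = False
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in list(d["generator"].items()):
            if isinstance(val, np.ndarray):
                d["generator"][key] = val.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        prior = d.pop("prior", {})
        mcmc = d.pop("mcmc", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in d.items()})
        gen = {k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
               if isinstance(v, list) and k in ("true_window", "population_centers")
               else v for k, v in gen.items()}
        cfg.generator = synthetic.GeneratorConfig(**gen)
        cfg.prior = PriorSpec(**prior)
        cfg.mcmc = McmcConfig(**mcmc)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # paths don't affect the science
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- loaders

def load_cohort(path, origin: pd.Timestamp) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "birth_day" not in df and "birth_date" in df:
        df["birth_day"] = (pd.to_datetime(df["birth_date"]) - origin).dt.days
    if "conception_day" not in df:
        df["conception_day"] = df["birth_day"] - 7 * df["gestational_age"]
    return df


def load_sources_and_panel(sources_path, panel_path, origin: pd.Timestamp,
                           n_days: int) -> tuple[synthetic.SourceSet, synthetic.PollutionPanel]:
    frame = pd.read_csv(sources_path)[["source_id", "regime", "x_km", "y_km"]]
    long = pd.read_csv(panel_path, parse_dates=["date"])
    long["day"] = (long["date"] - origin).dt.days
    sid_to_row = {sid: i for i, sid in enumerate(frame["source_id"])}
    values = np.full((len(frame), n_days), np.nan)
    rows = long["source_id"].map(sid_to_row).to_numpy()
    values[rows, long["day"].to_numpy()] = long["value"].to_numpy()
    active = ~np.isnan(values)
    sources = synthetic.SourceSet(frame, active, origin)
    panel = synthetic.PollutionPanel(values, frame["source_id"].to_numpy(), origin)
    return sources, panel


def load_exposure(path, n_weeks: int = synthetic.N_WEEKS
                  ) -> tuple[np.ndarray, exposure_mod.ExposureMatrix]:
    df = pd.read_csv(path)
    ids = df["birth_id"].unique()
    n = len(ids)
    raw = df.pivot(index="birth_id", columns="week", values="raw").loc[ids].to_numpy()
    std = df.pivot(index="birth_id", columns="week", values="standardized").loc[ids].to_numpy()
    valid = df.pivot(index="birth_id", columns="week", values="valid").loc[ids].to_numpy().astype(bool)
    pooled = raw[valid]
    rec = exposure_mod.ScalingRecord(float(pooled.mean()), float(pooled.std(ddof=1)))
    return ids, exposure_mod.ExposureMatrix(std, np.where(valid, raw, 0.0), valid, rec)


def draws_from_long(df: pd.DataFrame, model_tag: str) -> PosteriorDraws:
    wide = df.pivot(index="iteration", columns="parameter", values="value")
    theta_cols = [c for c in wide.columns if c.startswith(("week_", "trimester_"))]
    beta_cols = [c for c in wide.columns
                 if c not in theta_cols and c not in ("sigma2_theta", "phi")]
    weeks = None
    if theta_cols and theta_cols[0].startswith("week_"):
        theta_cols = sorted(theta_cols, key=lambda c: int(c.split("_")[1]))
        weeks = np.array([int(c.split("_")[1]) for c in theta_cols])
    return PosteriorDraws(
        beta=wide[beta_cols].to_numpy(), theta=wide[theta_cols].to_numpy(),
        sigma2_theta=wide["sigma2_theta"].to_numpy() if "sigma2_theta" in wide else None,
        phi=wide["phi"].to_numpy() if "phi" in wide else None,
        phi_acceptance_rate=None, model_tag=model_tag,
        beta_labels=beta_cols, theta_labels=list(theta_cols), week_ids=weeks)


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": gen.seed,
        "mcmc_seed": config.mcmc.seed,
        "stages": {},
        "row_counts": {},
    }
    state: dict = {}

    def _record(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"status": "ok",
                                     "seconds": round(time.time() - t0, 3)}

    try:
        for stage in config.stages:
            t0 = time.time()
            log.info("stage %s starting", stage)
            if stage == "generate":
                _stage_generate(config, outdir, state, manifest)
            elif stage == "expose":
                _stage_expose(config, outdir, state, manifest)
            elif stage == "fit":
                _stage_fit(config, outdir, state, manifest)
            elif stage == "summarize":
                _stage_summarize(config, outdir, state, manifest)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            _record(stage, t0)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_generate(config: RunConfig, outdir: Path, state: dict,
                    manifest: dict) -> None:
    gen = config.generator
    regimes = tuple(dict.fromkeys(config.metrics))
    sources = synthetic.gen_sources(gen, regimes=regimes)
    panel = synthetic.gen_ozone_panel(sources, gen)
    cohort = synthetic.gen_cohort(gen)

    # outcomes are driven by the first metric's standardized exposures
    primary = config.metrics[0]
    sub_sources = sources.regime(primary)
    sub_panel = synthetic.PollutionPanel(
        panel.values[(sources.frame["regime"] == primary).to_numpy()],
        sub_sources.frame["source_id"].to_numpy(), panel.origin)
    eligible, _ = exposure_mod.eligibility_filter(cohort, sub_sources, config.radius)
    exp = exposure_mod.build_exposure_matrix(eligible, sub_sources, sub_panel,
                                             config.radius)
    dm = design_mod.build_design(eligible)
    cohort_out, truth = synthetic.gen_outcomes(eligible, exp.values, dm.matrix, gen)

    synthetic.write_cohort(cohort_out, outdir / "births.csv", gen.origin)
    synthetic.write_sources(sources, outdir / "sources.csv")
    if config.write_panel:
        synthetic.write_panel(panel, outdir / "panel.csv")
    synthetic.write_config(gen, outdir / "generator.yaml")
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"intercept": truth["intercept"],
                   "theta": truth["theta"].tolist()}, fh, indent=2)
    state.update(cohort=cohort_out, sources=sources, panel=panel)
    manifest["row_counts"]["births"] = len(cohort_out)
    manifest["row_counts"]["sources"] = len(sources)
    manifest["row_counts"]["lbw_cases"] = int(cohort_out["lbw"].sum())


def _stage_expose(config: RunConfig, outdir: Path, state: dict,
                  manifest: dict) -> None:
    gen = config.generator
    if "cohort" not in state:
        state["cohort"] = load_cohort(outdir / "births.csv", gen.origin)
        state["sources"], state["panel"] = load_sources_and_panel(
            outdir / "sources.csv", outdir / "panel.csv", gen.origin, gen.n_days)
    cohort, sources, panel = state["cohort"], state["sources"], state["panel"]
    regimes = sources.frame["regime"].to_numpy()
    state["exposures"] = {}
    state["eligible"] = {}
    for metric in config.metrics:
        keep = regimes == metric
        sub = sources.regime(metric)
        sub_panel = synthetic.PollutionPanel(
            panel.values[keep], sub.frame["source_id"].to_numpy(), panel.origin)
        eligible, excl = exposure_mod.eligibility_filter(cohort, sub, config.radius)
        exp = exposure_mod.build_exposure_matrix(eligible, sub, sub_panel,
                                                 config.radius)
        exposure_mod.write_exposure(exp, eligible["birth_id"],
                                    outdir / f"exposure_{metric}.csv")
        exposure_mod.write_exclusions(excl, outdir / f"exclusions_{metric}.csv")
        state["exposures"][metric] = exp
        state["eligible"][metric] = eligible
        manifest["row_counts"][f"eligible_{metric}"] = len(eligible)
        manifest["row_counts"][f"excluded_{metric}"] = len(excl)


def _stage_fit(config: RunConfig, outdir: Path, state: dict,
               manifest: dict) -> None:
    gen = config.generator
    if "exposures" not in state:
        state["cohort"] = load_cohort(outdir / "births.csv", gen.origin)
        state["exposures"], state["eligible"] = {}, {}
        for metric in config.metrics:
            ids, exp = load_exposure(outdir / f"exposure_{metric}.csv")
            cohort = state["cohort"]
            state["exposures"][metric] = exp
            state["eligible"][metric] = cohort.set_index("birth_id").loc[ids].reset_index()
    state["fits"] = {}
    for metric in config.metrics:
        eligible = state["eligible"][metric]
        exp = state["exposures"][metric]
        dm = design_mod.build_design(eligible)
        design_mod.write_design(dm, outdir / f"design_{metric}.csv")
        y = eligible["lbw"].to_numpy(dtype=int)
        for model in config.models:
            variant = design_mod.MODEL_ALIASES[model]
            block = design_mod.build_exposure_block(exp, variant, config.max_week)
            draws = run_mcmc(y, dm.matrix, block.matrix, config.prior,
                             config.mcmc, model=variant,
                             beta_labels=dm.column_names,
                             theta_labels=block.labels, week_ids=block.weeks)
            tag = f"{metric}_{variant}"
            summaries_mod.draws_to_long(draws).to_csv(
                outdir / f"draws_{tag}.csv", index=False)
            fm = summaries_mod.compute_dic(draws, dm.matrix, block.matrix, y)
            with open(outdir / f"fit_{tag}.json", "w") as fh:
                json.dump({
                    "model": variant, "metric": metric,
                    "n": int(len(y)), "p": dm.p, "g": block.matrix.shape[1],
                    "phi_acceptance_rate": draws.phi_acceptance_rate,
                    "mc_errors": draws.mc_errors,
                    "dic": fm.dic, "p_d": fm.p_d,
                    "d_bar": fm.d_bar, "d_hat": fm.d_hat,
                    "seed": config.mcmc.seed,
                }, fh, indent=2)
            state["fits"][tag] = (draws, dm, block, y)
            manifest["row_counts"][f"draws_{tag}"] = draws.n_draws


def _stage_summarize(config: RunConfig, outdir: Path, state: dict,
                     manifest: dict) -> None:
    if "fits" not in state:
        state["fits"] = {}
        for metric in config.metrics:
            for model in config.models:
                variant = design_mod.MODEL_ALIASES[model]
                tag = f"{metric}_{variant}"
                df = pd.read_csv(outdir / f"draws_{tag}.csv")
                state["fits"][tag] = (draws_from_long(df, variant), None, None, None)
    by_metric: dict[str, summaries_mod.WindowSummaries] = {}
    tables = []
    for tag, (draws, *_rest) in state["fits"].items():
        disp = (config.display_max_week
                if draws.model_tag == "weekly_naive" else None)
        ws = summaries_mod.summarize_windows(draws, max_display_week=disp)
        t = ws.table.copy()
        t.insert(0, "run", tag)
        tables.append(t)
        if draws.model_tag == "weekly_structured":
            metric = tag.rsplit("_weekly_structured", 1)[0]
            by_metric[metric] = ws
        if config.make_plots:
            summaries_mod.plot_windows(ws, outdir / f"windows_{tag}.png", tag)
    pd.concat(tables, ignore_index=True).to_csv(outdir / "windows.csv", index=False)
    if len(by_metric) > 1:
        comp = summaries_mod.compare_metrics(by_metric)
        comp.summary.to_csv(outdir / "comparison.csv", index=False)
        comp.weekly_differences.to_csv(outdir / "comparison_weekly.csv", index=False)
    manifest["row_counts"]["summarized_runs"] = len(state["fits"])
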