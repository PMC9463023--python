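"""Readers, writers, configuration, and the pipeline driver.

The pipeline chains simulate → metrics → mixed models → path analysis into
one reproducible run: a single root seed feeds named substreams per stage,
every run writes a manifest (success or failure) with per-stage row counts
and warnings, and all tables are plain CSV with ISO calendar dates — the
season-day axis (days since Sep 1) is internal only.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glmm as glmm_mod
from . import metrics as metrics_mod
from . import pathmodel as path_mod
from .errors import ConfigurationError, DataError
from .simulate import (DielParams, Gap, SeasonalParams, SimulationTruth,
                       SyntheticColony, simulate_colony)

__all__ = [
    "RunConfig",
    "read_image_scores",
    "read_sites",
    "read_breeding",
    "write_colony",
    "truth_from_dict",
    "build_analysis_table",
    "run_pipeline",
    "derive_seed",
]

_SCORE_COLS = ["subcolony", "site_id", "season", "date", "time", "count"]


def derive_seed(root_seed: int, stage: int) -> int:
    """Independent 31-bit substream seed for one pipeline stage."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")


def read_image_scores(path) -> pd.DataFrame:
    """Schema-validated image-score table; adds the internal season-day."""
    df = pd.read_csv(path)
    _require_columns(df, _SCORE_COLS, path)
    c = df["count"].to_numpy()
    bad = np.flatnonzero((c < 0) | (c > 2) | (c != c.astype(int)))
    if bad.size:
        raise DataError(
            f"{path}: row {int(bad[0]) + 2}, column 'count': value "
            f"{df['count'].iloc[bad[0]]!r} outside {{0,1,2}}"
        )
    df["count"] = df["count"].astype(np.int8)
    df["date"] = pd.to_datetime(df["date"])
    df["site_id"] = df["site_id"].astype("category")
    return metrics_mod._ensure_season_day(df)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "subcolony", "quality"], path)
    q = df["quality"].to_numpy(float)
    bad = np.flatnonzero((q < 0) | (q > 1))
    if bad.size:
        raise DataError(
            f"{path}: row {int(bad[0]) + 2}, column 'quality': value "
            f"{q[bad[0]]!r} outside [0,1]"
        )
    return df


def read_breeding(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "season", "lay_date", "success"], path)
    s = df["success"].to_numpy()
    bad = np.flatnonzero(~np.isin(s, (0, 1)))
    if bad.size:
        raise DataError(
            f"{path}: row {int(bad[0]) + 2}, column 'success': value "
            f"{s[bad[0]]!r} not binary"
        )
    df["lay_date"] = pd.to_datetime(df["lay_date"])
    return df


# ---------------------------------------------------------------------------
# writers


def write_colony(colony: SyntheticColony, outdir) -> dict[str, int]:
    """Write image_scores/sites/breeding CSVs plus the truth echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores = colony.image_scores.copy()
    scores["date"] = pd.to_datetime(scores["date"]).dt.date.astype(str)
    scores[_SCORE_COLS].to_csv(outdir / "image_scores.csv", index=False)
    colony.sites.to_csv(outdir / "sites.csv", index=False)
    colony.breeding.to_csv(outdir / "breeding.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(colony.truth.to_dict(), fh, indent=1, default=str)
    return {
        "image_scores": len(scores),
        "sites": len(colony.sites),
        "breeding": len(colony.breeding),
    }


# ---------------------------------------------------------------------------
# configuration


def truth_from_dict(d: dict) -> SimulationTruth:
    """Build a SimulationTruth from a config mapping (YAML-friendly)."""
    d = dict(d)
    if "gap_spec" in d:
        d["gap_spec"] = tuple(
            g if isinstance(g, Gap) else Gap(**g) for g in d["gap_spec"]
        )
    if "diel_params" in d and isinstance(d["diel_params"], dict):
        d["diel_params"] = DielParams(**d["diel_params"])
    if "seasonal_params" in d and isinstance(d["seasonal_params"], dict):
        sp = dict(d["seasonal_params"])
        if "dips" in sp:
            sp["dips"] = tuple(tuple(x) for x in sp["dips"])
        d["seasonal_params"] = SeasonalParams(**sp)
    if "n_sites_per_subcolony" in d and isinstance(
            d["n_sites_per_subcolony"], list):
        d["n_sites_per_subcolony"] = tuple(d["n_sites_per_subcolony"])
    try:
        truth = SimulationTruth(**d)
    except TypeError as exc:
        raise ConfigurationError(f"invalid simulation truth: {exc}") from exc
    truth.validate()
    return truth


@dataclass
class RunConfig:
    """One pipeline run: either a simulation truth or input paths."""

    output_dir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None  # image_scores / sites / breeding paths
    presence_filters: tuple[str, ...] = ("any",)
    run_glmm: bool = True
    run_path: bool = True
    ci_method: str = "wald"
    mcmc_fast: bool = True
    mcmc: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of {simulate truth, input paths} must be given"
            )
        for f in self.presence_filters:
            if f not in metrics_mod.PRESENCE_FILTERS:
                raise ConfigurationError(f"unknown presence filter {f!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def mcmc_config(self) -> path_mod.MCMCConfig:
        seed = derive_seed(self.seed, 3)
        if self.mcmc:
            return path_mod.MCMCConfig(seed=self.mcmc.get("seed", seed),
                                       **{k: v for k, v in self.mcmc.items()
                                          if k != "seed"})
        if self.mcmc_fast:
            return path_mod.MCMCConfig.fast(seed=seed)
        return path_mod.MCMCConfig(seed=seed)


# ---------------------------------------------------------------------------
# analysis-table assembly


def _season_start_year(season: str) -> int:
    return int(str(season)[:4])


def build_analysis_table(metric_table: pd.DataFrame, sites: pd.DataFrame,
                         breeding: pd.DataFrame) -> pd.DataFrame:
    """Join metrics, site quality, and breeding outcomes per site-season.

    Adds subcolony-year grouping and the within-(subcolony × season)
    z-scores of quality and the three occupancy measures used as model
    covariates; lay date becomes a numeric day-of-season.
    """
    df = metric_table.merge(sites[["site_id", "subcolony", "quality"]],
                            on=["site_id", "subcolony"], how="left")
    br = breeding.copy()
    if not np.issubdtype(br["lay_date"].dtype, np.number):
        br["lay_date"] = pd.to_datetime(br["lay_date"])
        sep1 = br["season"].map(
            lambda s: pd.Timestamp(year=_season_start_year(s), month=9,
                                   day=1)
        )
        br["lay_day"] = (br["lay_date"] - sep1).dt.days.astype(float)
    else:
        br["lay_day"] = br["lay_date"].astype(float)
    df = df.merge(br[["site_id", "season", "lay_day", "success"]],
                  on=["site_id", "season"], how="left")
    df["subcolony_year"] = (df["subcolony"].astype(str) + "_"
                            + df["season"].astype(str))
    # observation-level factor: overdispersion term for aggregated binomials
    df["obs"] = df["site_id"].astype(str) + "_" + df["season"].astype(str)
    group = df["subcolony_year"]
    for raw, z in (("quality", "quality_z"), ("return_day", "return_z"),
                   ("occ_freq", "freq_z"), ("rti", "rti_z")):
        if df[raw].notna().sum() == 0:
            df[z] = np.nan
            continue
        out = np.full(len(df), np.nan)
        for g, idx in df.groupby(group).groups.items():
            v = df.loc[idx, raw].to_numpy(float)
            m = np.nanmean(v)
            s = np.nanstd(v, ddof=1)
            out[df.index.get_indexer(idx)] = (v - m) / s if s > 0 else np.nan
        df[z] = out
    return df


# ---------------------------------------------------------------------------
# model batteries


def _h1_specs() -> dict[str, glmm_mod.ModelSpec]:
    """Site quality → occupancy (return date, frequency, time investment)."""
    random = (glmm_mod.RandomTerm("site_id"),
              glmm_mod.RandomTerm("subcolony_year"))
    fixed = (("quality_z",), ("year",), ("quality_z", "year"))
    return {
        "h1_return": glmm_mod.ModelSpec("return_day", "gaussian",
                                        fixed=fixed, random=random),
        "h1_freq": glmm_mod.ModelSpec("occ_freq_num", "binomial",
                                      fixed=fixed, random=random,
                                      trials="occ_freq_den"),
        "h1_rti": glmm_mod.ModelSpec("rti_num", "binomial", fixed=fixed,
                                     random=random, trials="rti_den"),
    }


def _assoc_specs() -> dict[str, glmm_mod.ModelSpec]:
    """Associations among the occupancy measures."""
    random = (glmm_mod.RandomTerm("site_id"),
              glmm_mod.RandomTerm("subcolony_year"))
    return {
        "assoc_freq": glmm_mod.ModelSpec(
            "occ_freq_num", "binomial", fixed=(("return_z",),),
            random=random, trials="occ_freq_den"),
        "assoc_rti": glmm_mod.ModelSpec(
            "rti_num", "binomial",
            fixed=(("return_z",), ("freq_z",), ("return_z", "freq_z")),
            random=random, trials="rti_den"),
    }


def _h2_specs() -> dict[str, glmm_mod.ModelSpec]:
    """Occupancy → breeding timing (2a) and success (2b)."""
    random = (glmm_mod.RandomTerm("site_id"),
              glmm_mod.RandomTerm("subcolony_year"))
    fixed = (("return_z",), ("freq_z",), ("rti_z",),
             ("return_z", "freq_z"), ("return_z", "rti_z"),
             ("freq_z", "rti_z"), ("return_z", "freq_z", "rti_z"))
    return {
        "h2a_laydate": glmm_mod.ModelSpec("lay_day", "gaussian", fixed=fixed,
                                          random=random),
        "h2b_success": glmm_mod.ModelSpec("success", "bernoulli",
                                          fixed=fixed, random=random),
    }


_HYPOTHESIS_SPECS = {
    "assoc": _assoc_specs, "h1": _h1_specs, "h2": _h2_specs,
}


def _drop_collinear(spec, flagged_pairs):
    """Remove candidates containing a flagged covariate pair."""
    def keeps(cand):
        vars_ = {v for t in cand.fixed for v in t}
        return not any(a in vars_ and b in vars_ for a, b in flagged_pairs)
    return keeps


def run_glmm_battery(table: pd.DataFrame, hypotheses=("assoc", "h1", "h2"),
                     ci_method: str = "wald") -> dict:
    """AIC selection plus the chosen-model report for each hypothesis model.

    Returns {model name: {selection table, chosen fit summary, R², KS check
    for Gaussian responses, collinearity screen}}.
    """
    table = table.copy()
    table["year"] = table["season"].astype(str)
    screen = glmm_mod.collinearity_screen(
        table, [c for c in ("return_z", "freq_z", "rti_z", "quality_z")
                if c in table and table[c].notna().any()]
    )
    flagged = [(r.var_a, r.var_b) for r in screen.itertuples()
               if r.flagged]
    out = {"collinearity": screen}
    for hyp in hypotheses:
        for name, spec in _HYPOTHESIS_SPECS[hyp]().items():
            rows = table.dropna(subset=[v for v in spec.variables()
                                        if v in table.columns])
            if len(rows) < 10:
                out[name] = {"error": f"too few complete rows ({len(rows)})"}
                continue
            candidates = glmm_mod.candidate_specs(spec)
            keeps = _drop_collinear(spec, flagged)
            candidates = [c for c in candidates if keeps(c)]
            sel = glmm_mod.aic_select(candidates, rows)
            fit = sel.chosen
            fit.ci = glmm_mod.confint_fixed(fit, method=ci_method)
            marg, cond = glmm_mod.r_squared_nakagawa(fit)
            entry = {
                "selection": sel.table,
                "rule": sel.rule,
                "chosen": fit.spec.label(),
                "summary": fit.summary(),
                "aic": fit.aic,
                "loglik": fit.loglik,
                "r2_marginal": marg,
                "r2_conditional": cond,
                "converged": fit.converged,
                "boundary": fit.boundary,
                "notes": list(fit.notes),
                "variance_components": fit.variance_components,
            }
            if spec.family == "gaussian":
                entry["ks_normality"] = glmm_mod.ks_normality(
                    rows[spec.response]
                )
            out[name] = entry
    return out


# ---------------------------------------------------------------------------
# pipeline driver


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages in order; always writes the manifest.

    Any stage failure halts the run with the manifest recording the stages
    completed so far and the error, tagged by stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "colonywatch",
        "version": __import__("colonywatch").__version__,
        "config": _jsonable({k: v for k, v in asdict(config).items()}),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "setup"
    try:
        # -- stage 1: data in -------------------------------------------------
        stage = "simulate" if config.simulate is not None else "read"
        if config.simulate is not None:
            truth_dict = dict(config.simulate)
            truth_dict.setdefault("seed", derive_seed(config.seed, 0))
            truth = truth_from_dict(truth_dict)
            colony = simulate_colony(truth)
            counts = write_colony(colony, outdir)
            scores, sites, breeding = (colony.image_scores, colony.sites,
                                       colony.breeding)
            manifest["stages"][stage] = counts
        else:
            scores = read_image_scores(config.inputs["image_scores"])
            sites = read_sites(config.inputs["sites"])
            breeding = read_breeding(config.inputs["breeding"])
            manifest["stages"][stage] = {
                "image_scores": len(scores), "sites": len(sites),
                "breeding": len(breeding),
            }

        # -- stage 2: metrics -------------------------------------------------
        stage = "metrics"
        tabs = []
        for f in config.presence_filters:
            tabs.append(metrics_mod.occupancy_metrics(scores,
                                                      presence_filter=f))
        metric_table = pd.concat(tabs, ignore_index=True)
        metric_table.to_csv(outdir / "metrics.csv", index=False)
        daily, hourly = metrics_mod.colony_summaries(scores)
        daily.to_csv(outdir / "daily_summary.csv", index=False)
        hourly.to_csv(outdir / "hourly_summary.csv", index=False)
        never = int(metric_table["return_day"].isna().sum())
        if never:
            manifest["warnings"].append(
                f"{never} site-season rows never occupied (excluded from "
                "models needing a return date)"
            )
        manifest["stages"][stage] = {"metrics_rows": len(metric_table)}

        # -- stage 3: mixed models -------------------------------------------
        results = {}
        if config.run_glmm:
            stage = "glmm"
            for f in config.presence_filters:
                tab = build_analysis_table(
                    metric_table[metric_table["presence_filter"] == f],
                    sites, breeding,
                )
                res = run_glmm_battery(tab, ci_method=config.ci_method)
                results[f] = res
                fits_dir = outdir / "fits"
                fits_dir.mkdir(exist_ok=True)
                sel_rows = []
                for name, entry in res.items():
                    if name == "collinearity":
                        continue
                    with open(fits_dir / f"{name}_{f}.json", "w") as fh:
                        json.dump(_jsonable(entry), fh, indent=1)
                    if "selection" in entry:
                        s = entry["selection"].copy()
                        s.insert(0, "model", name)
                        s.insert(1, "presence_filter", f)
                        sel_rows.append(s)
                if sel_rows:
                    pd.concat(sel_rows, ignore_index=True).to_csv(
                        outdir / f"selection_{f}.csv", index=False
                    )
                nonconv = [n for n, e in res.items()
                           if isinstance(e, dict)
                           and e.get("converged") is False]
                if nonconv:
                    manifest["warnings"].append(
                        f"non-convergent fits ({f}): {nonconv}"
                    )
            manifest["stages"][stage] = {
                "models": sum(len(r) - 1 for r in results.values())
            }

        # -- stage 4: path analysis ------------------------------------------
        if config.run_path:
            stage = "pathmodel"
            tab = build_analysis_table(
                metric_table[metric_table["presence_filter"] == "any"],
                sites, breeding,
            )
            pdat = tab.dropna(
                subset=["quality", "return_day", "occ_freq", "lay_day",
                        "success"]
            )[["site_id", "quality", "return_day", "occ_freq", "lay_day",
               "success"]].rename(columns={"lay_day": "lay_date"})
            pdat = path_mod.standardize_path_data(pdat)
            posts = path_mod.fit_all_pathways(pdat,
                                              config=config.mcmc_config())
            path_mod.pathways_table(posts).to_csv(
                outdir / "pathways.csv", index=False
            )
            diag = path_mod.diagnostics_table(posts)
            diag.to_csv(outdir / "diagnostics.csv", index=False)
            _write_chains(posts, outdir / "chains")
            bad = diag[diag["rhat"] > 1.05]
            if len(bad):
                manifest["warnings"].append(
                    f"R-hat > 1.05 for {bad['variable'].tolist()}"
                )
            manifest["stages"][stage] = {
                "n_obs": int(posts[0].n_obs),
                "max_rhat": float(diag["rhat"].max()),
                "min_ess": float(diag["ess"].min()),
            }
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        raise
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=1)
    return manifest


def _write_chains(posteriors, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(exist_ok=True)
    seen = set()
    frames = []
    for p in posteriors:
        for name, arr in p.draws.items():
            if name in ("pathway", "direct"):
                name = f"{p.pathway.name}.{name}"
            if name in seen:
                continue
            seen.add(name)
            for c in range(arr.shape[0]):
                frames.append(pd.DataFrame({
                    "variable": name, "chain": c,
                    "draw": np.arange(arr.shape[1]), "value": arr[c],
                }))
    long = pd.concat(frames, ignore_index=True)
    try:
        long.to_parquet(outdir / "chains.parquet", index=False)
    except Exception:  # pyarrow unavailable: plain CSV
        long.to_csv(outdir / "chains.csv", index=False)
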