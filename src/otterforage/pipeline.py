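"""One-command orchestration of the full analysis.

simulate -> precompute Dirichlet precisions -> fit the state-space model ->
resolve counterfactual scenarios -> intertidal/census trend stage -> report.

Every stage writes its outputs into a run directory and failures abort with
a stage tag while preserving partial outputs. A fixed seed makes the whole
run deterministic; per-stage generators are spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ofio
from .foraging import dirichlet_precision
from .intertidal import census_prepost, fit_gompertz, fit_trend_spline, prepost_summary
from .model import ModelConfig, PosteriorSamples, fit_model
from .scenarios import ScenarioSpec, item_values_from_profiles, resolve_scenario
from .synthetic import (
    CensusConfig,
    GroundTruthConfig,
    IntertidalConfig,
    PreyProfile,
    RegimeShift,
    generate_ground_truth,
    simulate_census,
    simulate_intertidal,
    simulate_sofa_outputs,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    seed: int = 0
    truth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    n_draws: int = 1000
    missing_frac: float = 0.0
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        n_warmup=1500, n_steps=4000, thin=4,
        # the overall-density direction is prior-identified and converges
        # slowly at full problem size; the orchestrated run reports
        # diagnostics instead of refusing to finish
        enforce_convergence=False,
    ))
    scenarios: tuple[str, ...] = (
        "baseline", "no_urchin_increase", "no_mussel_increase", "neither"
    )
    scenario_cutoff: int = 2012
    reference_years: tuple[int, int] = (2007, 2012)
    ssw_year: int = 2013
    intertidal: IntertidalConfig = field(default_factory=IntertidalConfig)
    census: CensusConfig = field(default_factory=CensusConfig)

    def __post_init__(self) -> None:
        ids = set(self.truth.prey_ids)
        from .scenarios import SCENARIO_FROZEN_PREY
        for name in self.scenarios:
            for p in SCENARIO_FROZEN_PREY.get(name, ()):
                if p not in ids:
                    raise ValueError(
                        f"scenario {name!r} references prey {p!r} absent "
                        "from the synthetic configuration"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        if "truth" in kw:
            t = dict(kw["truth"])
            if "prey" in t:
                t["prey"] = [PreyProfile(**p) for p in t["prey"]]
            if "regime_shifts" in t:
                t["regime_shifts"] = [RegimeShift(**s) for s in t["regime_shifts"]]
            kw["truth"] = GroundTruthConfig(**t)
        if "model" in kw:
            kw["model"] = ModelConfig(**kw["model"])
        if "intertidal" in kw:
            kw["intertidal"] = IntertidalConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in kw["intertidal"].items()}
            )
        if "census" in kw:
            kw["census"] = CensusConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in kw["census"].items()}
            )
        if "scenarios" in kw:
            kw["scenarios"] = tuple(kw["scenarios"])
        return cls(**kw)

    @classmethod
    def small(cls, seed: int = 0) -> "RunConfig":
        """A reduced configuration for smoke runs: 4 prey, 2008-2016."""
        prey = [p for p in GroundTruthConfig().prey
                if p.prey_id in ("cancrid_crab", "clam", "urchin", "mussel",
                                 "snail", "worm")]
        truth = GroundTruthConfig(
            prey=prey,
            year_start=2008, year_end=2016,
            regime_shifts=[
                RegimeShift("urchin", 2014, 1, 0.43),
                RegimeShift("mussel", 2014, 3, 1.0),
                RegimeShift("cancrid_crab", 2014, 1, -1.05),
            ],
        )
        model = ModelConfig(n_warmup=300, n_steps=600, thin=2,
                            enforce_convergence=False)
        intertidal = IntertidalConfig(n_sizes=20)
        return cls(seed=seed, truth=truth, n_draws=300, model=model,
                   reference_years=(2008, 2012), intertidal=intertidal)


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _stage(tag: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(
                    f"stage '{tag}' failed: {e}\n{traceback.format_exc()}"
                ) from e
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(cfg: RunConfig, outdir: Path):
    s = _seeds(cfg.seed, 4)
    truth = generate_ground_truth(cfg.truth, seed=s[0])
    obs = simulate_sofa_outputs(truth, n_draws=cfg.n_draws, seed=s[1],
                                missing_frac=cfg.missing_frac)
    surveys = simulate_intertidal(cfg.intertidal, seed=s[2])
    census = simulate_census(cfg.census, seed=s[3])
    data = outdir / "data"
    ofio.write_foraging(obs, data)
    ofio.write_truth_json(truth, data / "truth.json")
    ofio.write_intertidal(surveys, data)
    ofio.write_census(census, data / "census.csv")
    return truth, obs, surveys, census


@_stage("fit")
def stage_fit(cfg: RunConfig, obs, outdir: Path) -> PosteriorSamples:
    T = len(obs.years)
    tau = np.array([dirichlet_precision(obs.eta_draws[t]) for t in range(T)])
    ps = fit_model(obs, cfg.model, tau=tau)
    mdir = outdir / "model"
    mdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"year": obs.years, "tau": tau}).to_csv(
        mdir / "tau.csv", index=False
    )
    ps.summary().to_csv(mdir / "posterior_summary.csv", index=False)
    ps.diagnostics.to_csv(mdir / "diagnostics.csv", index=False)
    _draws_frame(ps).to_parquet(mdir / "draws.parquet", index=False)
    return ps


def _draws_frame(ps: PosteriorSamples) -> pd.DataFrame:
    n, K = ps.mu.shape
    T = ps.Delta.shape[-1]
    cols = {}
    for i, p in enumerate(ps.prey_ids):
        cols[f"mu[{p}]"] = ps.mu[:, i]
        cols[f"sigma_D[{p}]"] = ps.sigma_D[:, i]
        cols[f"sigma_E[{p}]"] = ps.sigma_E[:, i]
        for t, y in enumerate(ps.years):
            cols[f"Delta[{p},{y}]"] = ps.Delta[:, i, t]
    return pd.DataFrame(cols)


@_stage("scenarios")
def stage_scenarios(cfg: RunConfig, ps: PosteriorSamples, obs, outdir: Path):
    sdir = outdir / "scenarios"
    sdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_seeds(cfg.seed, 6)[4])
    item_values = item_values_from_profiles(
        cfg.truth.prey, obs=obs, n_draws=ps.n_draws, rng=rng
    )
    results = {}
    energy, predation, effort = [], [], []
    scen_seeds = _seeds(cfg.seed + 1, len(cfg.scenarios))
    for name, sseed in zip(cfg.scenarios, scen_seeds):
        spec = ScenarioSpec.named(
            name, seed=sseed, cutoff_year=cfg.scenario_cutoff,
            reference_years=cfg.reference_years,
        )
        res = resolve_scenario(ps, spec, item_values)
        results[name] = res
        energy.append(res.to_frame())
        predation.append(res.predation)
        effort.append(res.effort)
    pd.concat(energy).to_csv(sdir / "energy.csv", index=False)
    pd.concat(predation).to_csv(sdir / "predation.csv", index=False)
    pd.concat(effort).to_csv(sdir / "effort.csv", index=False)
    return results


@_stage("intertidal")
def stage_intertidal(cfg: RunConfig, surveys, census, outdir: Path):
    idir = outdir / "intertidal"
    idir.mkdir(parents=True, exist_ok=True)
    summary = prepost_summary(surveys, cutoff=cfg.ssw_year,
                              pre_years=cfg.intertidal.pre_years,
                              post_years=cfg.intertidal.post_years)
    summary.to_frame().to_csv(idir / "prepost_comparisons.csv", index=False)
    for name, table in summary.tables.items():
        table.to_csv(idir / f"freq_{name}.csv", index=False)

    df = pd.DataFrame(
        [(s.site_id, s.year, s.pisaster_density, s.mussel_cover)
         for s in surveys],
        columns=["site_id", "year", "pisaster", "cover"],
    )
    yearly = df.groupby("year").agg(
        pisaster=("pisaster", "mean"), cover=("cover", "mean")
    ).reset_index()

    pre = yearly.dropna(subset=["pisaster"])
    pre = pre[pre["year"] < cfg.ssw_year]
    gomp = fit_gompertz(pre["year"].to_numpy(), pre["pisaster"].to_numpy())
    extrap = gomp.extrapolate(int(pre["year"].max()) + 1, cfg.ssw_year - 1)
    pd.DataFrame({
        "parameter": ["A", "b", "k", "residual_scale"],
        "value": [gomp.A, gomp.b, gomp.k, gomp.residual_scale],
    }).to_csv(idir / "gompertz_fit.csv", index=False)
    extrap.to_csv(idir / "gompertz_extrapolation.csv", index=False)

    cover_trend = fit_trend_spline(yearly["year"], yearly["cover"])
    pd.DataFrame({
        "year": cover_trend.years, "fitted": cover_trend.fitted,
        "stderr": cover_trend.stderr,
    }).to_csv(idir / "cover_spline.csv", index=False)

    cdf = census.to_frame()
    census_trend = fit_trend_spline(cdf["year"], cdf["count"])
    cpp = census_prepost(census, cutoff=cfg.ssw_year)
    cpp.to_csv(idir / "census_prepost.csv", index=False)
    return {
        "summary": summary, "gompertz": gomp, "extrapolation": extrap,
        "cover_trend": cover_trend, "census_trend": census_trend,
        "census_prepost": cpp, "yearly": yearly,
    }


@_stage("report")
def stage_report(cfg: RunConfig, ps, scenario_results, intertidal_out,
                 census, outdir: Path):
    from . import plotting

    fdir = outdir / "figures"
    fdir.mkdir(parents=True, exist_ok=True)
    base = scenario_results["baseline"]
    plotting.plot_effort(base, ssw_year=cfg.ssw_year).savefig(
        fdir / "effort_trajectories.png", dpi=150)
    plotting.plot_scenarios(scenario_results, ssw_year=cfg.ssw_year).savefig(
        fdir / "scenario_comparison.png", dpi=150)
    yearly = intertidal_out["yearly"]
    plotting.plot_trend(
        yearly["year"], yearly["cover"], intertidal_out["cover_trend"],
        ssw_year=cfg.ssw_year, ylabel="mussel cover (%)",
    ).savefig(fdir / "cover_trend.png", dpi=150)
    cdf = census.to_frame()
    plotting.plot_trend(
        cdf["year"], cdf["count"], intertidal_out["census_trend"],
        ssw_year=cfg.ssw_year, ylabel="independent sea otters",
    ).savefig(fdir / "census_trend.png", dpi=150)
    plotting.plot_prepost_histograms(intertidal_out["summary"]).savefig(
        fdir / "prepost_histograms.png", dpi=150)

    # headline contrasts
    eff = base.effort
    rows = []
    pre = eff["year"] < cfg.ssw_year
    for prey in ("mussel", "urchin"):
        if prey not in ps.prey_ids:
            continue
        sub = eff[eff["prey_id"] == prey]
        pre_m = sub.loc[sub["year"] < cfg.ssw_year, "mean"].mean()
        post_m = sub.loc[sub["year"] >= cfg.ssw_year, "mean"].mean()
        rows += [
            (f"{prey}_effort_pre_pct", 100 * pre_m),
            (f"{prey}_effort_post_pct", 100 * post_m),
            (f"{prey}_effort_fold_change", post_m / pre_m),
        ]
    e = base
    pre_e = e.energy_mean[e.years < cfg.ssw_year].mean()
    post_e = e.energy_mean[e.years >= cfg.ssw_year].mean()
    rows += [("energy_pre_kcal_min", pre_e), ("energy_post_kcal_min", post_e)]
    cpp = intertidal_out["census_prepost"]
    rows += [
        ("census_pre_mean", float(cpp.loc[cpp.period == "pre", "mean"].iloc[0])),
        ("census_post_mean", float(cpp.loc[cpp.period == "post", "mean"].iloc[0])),
    ]
    for name, comp in intertidal_out["summary"].comparisons.items():
        rows += [(f"{name}_t", comp.t), (f"{name}_p", comp.p)]
    summary = pd.DataFrame(rows, columns=["statistic", "value"])
    summary.to_csv(outdir / "summary.csv", index=False)

    diag = ps.diagnostics
    report = [
        "# Pipeline run report",
        "",
        f"seed: {cfg.seed}",
        f"prey types: {len(ps.prey_ids)}; years "
        f"{ps.years[0]}-{ps.years[-1]}; posterior draws {ps.n_draws}",
        f"sampler: {cfg.model.chains} chains x {cfg.model.n_steps} sweeps "
        f"(warmup {cfg.model.n_warmup})",
        f"worst R-hat {diag.rhat.max():.3f}; smallest bulk ESS "
        f"{diag.ess.min():.0f} (see model/diagnostics.csv)",
        "",
        "## Headline contrasts",
        "",
        summary.to_string(index=False),
        "",
    ]
    (outdir / "report.md").write_text("\n".join(report))
    return summary


def run_pipeline(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Run the full pipeline into ``outdir``; returns the summary table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(_config_dict(config), sort_keys=False)
    )
    truth, obs, surveys, census = stage_simulate(config, outdir)
    ps = stage_fit(config, obs, outdir)
    scen = stage_scenarios(config, ps, obs, outdir)
    inter = stage_intertidal(config, surveys, census, outdir)
    return stage_report(config, ps, scen, inter, census, outdir)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x

    return clean(d)
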