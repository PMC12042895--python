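"""Tidy CSV/JSON serialization of the synthetic data streams and posteriors.

One file per table; years are calendar integers, cover in percent (0-100),
distances in meters, sizes in mm, energy in kcal. A JSON sidecar records
the ground-truth parameters and seeds of a simulated data set.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    CensusSeries,
    GroundTruth,
    IntertidalSurvey,
    ObservedForaging,
    PreyProfile,
    RegimeShift,
)

__all__ = [
    "write_foraging",
    "read_foraging",
    "write_truth_json",
    "read_truth_json",
    "write_intertidal",
    "read_intertidal",
    "write_census",
    "read_census",
]


def write_foraging(obs: ObservedForaging, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T, n, K = obs.eta_draws.shape
    years = np.repeat(obs.years, n * K)
    draws = np.tile(np.repeat(np.arange(n), K), T)
    prey = np.tile(obs.prey_ids, T * n)
    pd.DataFrame(
        {"year": years, "draw": draws, "prey_id": prey,
         "eta": obs.eta_draws.reshape(-1)}
    ).to_csv(outdir / "effort_draws.csv", index=False)

    rows = [
        (p, int(y), obs.mu_obs[i, t])
        for i, p in enumerate(obs.prey_ids)
        for t, y in enumerate(obs.years)
    ]
    pd.DataFrame(rows, columns=["prey_id", "year", "mu_obs"]).to_csv(
        outdir / "intake_obs.csv", index=False
    )
    n_item = obs.size_draws.shape[1]
    pd.DataFrame({
        "prey_id": np.repeat(obs.prey_ids, n_item),
        "draw": np.tile(np.arange(n_item), K),
        "size_mm": obs.size_draws.reshape(-1),
        "caloric_density": obs.cal_draws.reshape(-1),
    }).to_csv(outdir / "item_draws.csv", index=False)


def read_foraging(datadir: str | Path) -> ObservedForaging:
    datadir = Path(datadir)
    eff = pd.read_csv(datadir / "effort_draws.csv")
    intake = pd.read_csv(datadir / "intake_obs.csv")
    items = pd.read_csv(datadir / "item_draws.csv")
    years = np.sort(eff["year"].unique())
    # preserve the original prey order via the intake table
    prey_ids = list(intake["prey_id"].drop_duplicates())
    n = eff["draw"].max() + 1
    K, T = len(prey_ids), len(years)
    pidx = {p: i for i, p in enumerate(prey_ids)}
    yidx = {int(y): t for t, y in enumerate(years)}
    eta = np.empty((T, n, K))
    eta[
        eff["year"].map(yidx), eff["draw"],
        eff["prey_id"].map(pidx),
    ] = eff["eta"]
    mu_obs = np.full((K, T), np.nan)
    mu_obs[intake["prey_id"].map(pidx), intake["year"].map(yidx)] = intake["mu_obs"]
    n_item = items["draw"].max() + 1
    size = np.empty((K, n_item))
    cal = np.empty((K, n_item))
    size[items["prey_id"].map(pidx), items["draw"]] = items["size_mm"]
    cal[items["prey_id"].map(pidx), items["draw"]] = items["caloric_density"]
    return ObservedForaging(
        prey_ids=prey_ids, years=years, eta_draws=eta, mu_obs=mu_obs,
        size_draws=size, cal_draws=cal,
    )


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "years": truth.years.tolist(),
        "prey": [asdict(p) for p in truth.prey],
        "Delta": truth.Delta.tolist(),
        "sigma_D": truth.sigma_D.tolist(),
        "sigma_E": truth.sigma_E.tolist(),
        "tau": truth.tau.tolist(),
        "regime_shifts": [asdict(s) for s in truth.regime_shifts],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        prey=[PreyProfile(**p) for p in d["prey"]],
        years=np.array(d["years"]),
        Delta=np.array(d["Delta"]),
        sigma_D=np.array(d["sigma_D"]),
        sigma_E=np.array(d["sigma_E"]),
        tau=np.array(d["tau"]),
        regime_shifts=[RegimeShift(**s) for s in d["regime_shifts"]],
        seed=d["seed"],
    )


def write_intertidal(surveys: list[IntertidalSurvey], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(s.site_id, s.year, s.pisaster_density, s.mussel_cover) for s in surveys],
        columns=["site_id", "year", "pisaster_density", "mussel_cover"],
    ).to_csv(outdir / "intertidal_surveys.csv", index=False)
    grids = []
    sizes = []
    for s in surveys:
        g = s.grid_presence.copy()
        g.insert(0, "year", s.year)
        g.insert(0, "site_id", s.site_id)
        grids.append(g)
        sizes.append(pd.DataFrame({
            "site_id": s.site_id, "year": s.year,
            "size_mm": np.asarray(s.mussel_sizes_mm),
        }))
    pd.concat(grids).to_csv(outdir / "intertidal_grid.csv", index=False)
    pd.concat(sizes).to_csv(outdir / "mussel_sizes.csv", index=False)


def read_intertidal(datadir: str | Path) -> list[IntertidalSurvey]:
    datadir = Path(datadir)
    surveys = pd.read_csv(datadir / "intertidal_surveys.csv")
    grid = pd.read_csv(datadir / "intertidal_grid.csv")
    sizes = pd.read_csv(datadir / "mussel_sizes.csv")
    out = []
    for _, row in surveys.iterrows():
        key = (grid["site_id"] == row.site_id) & (grid["year"] == row.year)
        skey = (sizes["site_id"] == row.site_id) & (sizes["year"] == row.year)
        out.append(IntertidalSurvey(
            site_id=row.site_id, year=int(row.year),
            pisaster_density=row.pisaster_density,
            mussel_cover=row.mussel_cover,
            grid_presence=grid.loc[key, ["transect", "distance_m", "present"]]
            .reset_index(drop=True),
            mussel_sizes_mm=sizes.loc[skey, "size_mm"].to_numpy(),
        ))
    return out


def write_census(series: CensusSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_census(path: str | Path) -> CensusSeries:
    df = pd.read_csv(path)
    return CensusSeries(
        years=df["year"].to_numpy(), counts=df["count"].to_numpy()
    )
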