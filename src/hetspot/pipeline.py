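"""End-to-end pipeline driver.

Runs synth (optional) → tessellation → standardization → per-setting
KDE + Monte Carlo → consensus → geographical detector → GTWR, writing every
artifact plus a JSON manifest (specs, seed, per-stage wall time) so a run
is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geodetector, gtwr, io, standardization, synthetic_county
from .hetkde import KdeSpec, standard_settings
from .mc_significance import McSpec, consensus_overlap, run_mc

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Single-file configuration for a pipeline run (YAML on disk)."""

    out_dir: str = "hetspot_run"
    seed: int = 0
    # synthetic generation ("small" or "full"); set to None to load inputs
    synth: str | None = "small"
    n_villages: int | None = None
    villages_path: str | None = None
    cases_path: str | None = None
    kde_settings: list[dict] = field(default_factory=lambda: [{"bandwidth_mode": "fixed", "h": 1000.0}])
    k_sims: int = 999
    r_realizations: int = 5
    alpha: float = 0.005
    quorum: int = 2
    detector_classes: int = 5
    gtwr_bandwidth: float = 3000.0
    gtwr_lambda_t: float = 1000.0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _kde_specs(config: RunConfig) -> list[KdeSpec]:
    if config.kde_settings == "standard":
        return standard_settings()
    return [KdeSpec(**s) for s in config.kde_settings]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"t0": time.time()}

    def done(name):
        manifest["stages"][name]["seconds"] = round(
            time.time() - manifest["stages"][name].pop("t0"), 3
        )

    # ---- synth / load ----
    stage("synth")
    if config.synth is not None:
        if config.synth == "full":
            cfg = synthetic_county.default_config(seed=config.seed)
        else:
            cfg = synthetic_county.small_config(
                seed=config.seed,
                rr_clusters=(
                    synthetic_county.RRCluster((5_000.0, 5_000.0), 1_500.0, 3.0),
                ),
            )
        if config.n_villages:
            from dataclasses import replace

            cfg = replace(cfg, n_villages=config.n_villages)
        county = synthetic_county.generate(cfg)
        io.write_points_geojson(out / "villages.geojson", county.village_ids, county.villages)
        io.write_cases_csv(out / "cases.csv", county.cases)
        county.truth.rename("rr").to_csv(out / "truth.csv")
    else:
        raise NotImplementedError(
            "external-data runs: load villages/cases with hetspot.io and call the "
            "library stages directly; the CLI drives the bundled synthetic county"
        )
    done("synth")

    # ---- standardization ----
    stage("standardize")
    vpop = county.village_pop()
    by_stratum = county.cases_by_stratum()
    std_rates = standardization.compute_standard_rates(by_stratum, vpop.sum(axis=0))
    expected = standardization.compute_expected_cases(
        vpop, std_rates, county.cases_by_village()
    )
    expected.to_csv(out / "expected_cases.csv")
    bg = standardization.expected_surface(
        expected, county.partition, county.population.total_surface()
    )
    bg.write_ascii(out / "expected_surface.asc")
    done("standardize")

    # ---- KDE + MC per setting, consensus ----
    stage("hotspots")
    mc_spec = McSpec(config.k_sims, config.r_realizations, config.alpha, seed=config.seed)
    masks = []
    counts_by_village = county.cases_by_village()
    for spec in _kde_specs(config):
        grids = run_mc(
            counts_by_village, county.partition, bg, spec, mc_spec,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 10])),
        )
        label = spec.label()
        grids.mean_p.write_ascii(out / f"mean_p_{label}.asc")
        grids.std_p.write_ascii(out / f"std_p_{label}.asc")
        grids.hotspot.write_ascii(out / f"hotspot_{label}.asc")
        masks.append(grids.hotspot)
    consensus = consensus_overlap(masks)
    consensus.write_ascii(out / "consensus_counts.asc")
    certain = consensus_overlap(masks, quorum=config.quorum)
    certain.write_ascii(out / "consensus_certain.asc")
    done("hotspots")

    # ---- geographical detector ----
    stage("detect")
    pop_total = expected["population"]
    rate = county.cases_by_village() / pop_total.replace(0, np.nan) * 1e5
    rate = rate.fillna(0.0)
    qtab = geodetector.factor_table(
        rate, county.covariates, n_classes=config.detector_classes, seed=config.seed
    )
    qtab.to_csv(out / "detector_q.csv")
    done("detect")

    # ---- GTWR ----
    stage("gtwr")
    rows = []
    for year in county.config.years:
        cv = county.cases_by_village(year) / pop_total.replace(0, np.nan) * 1e5
        for vid in county.village_ids:
            rows.append({"village_id": vid, "year": year, "rate": float(cv.get(vid, 0.0))})
    obs = pd.DataFrame(rows)
    cov = county.covariates.loc[obs["village_id"]].reset_index(drop=True)
    coords = county.villages[
        [county.village_ids.index(v) for v in obs["village_id"]]
    ]
    spec = gtwr.GtwrSpec(config.gtwr_bandwidth, config.gtwr_lambda_t, ridge=1e-8)
    fit = gtwr.fit_gtwr(
        cov[["dist_river", "dist_facility", "elevation"]],
        obs["rate"],
        coords,
        obs["year"],
        spec,
    )
    fit.beta.assign(village_id=obs["village_id"].to_numpy(), year=obs["year"].to_numpy()).to_csv(
        out / "gtwr_coefficients.csv", index=False
    )
    _, signs = gtwr.significant_coefficients(fit, alpha=0.01)
    signs.to_csv(out / "gtwr_sign_summary.csv")
    manifest["gtwr_r2"] = fit.r2
    done("gtwr")

    manifest["n_villages"] = len(county.village_ids)
    manifest["total_cases"] = int(county.cases["count"].sum())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
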