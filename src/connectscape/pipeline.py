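"""End-to-end scenario driver: synthetic landscape -> suitability models ->
resistance matrix -> corridors, with manifesting and reproducible seeds.

The default scenario matrix is {sensitive, tolerant} x {occupancy, SSF-All,
SSF-Travel} x {linear, exp_c3, exp_c8} = 18 group resistance surfaces, each
followed by corridor and pinch-point mapping between occupancy-derived core
areas.  All randomness flows from one root seed, split per stage with
``numpy.random.SeedSequence(root).spawn`` in a fixed order (landscape,
detections, occupancy chains, one stream per simulated individual, SSF
control sampling), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import connect_cores
from .covariates import screen_collinearity, standardize_stack
from .occupancy import (GROUP_DEFAULT_THRESHOLDS, OccupancyModelSpec,
                        extract_cores, fit_community_occupancy,
                        occupancy_area_threshold, predict_psi)
from .raster import Raster
from .resistance import CURVES, ResistanceSurface, burn_barriers, combine_group, transform
from .ssf import TRAVEL_THRESHOLDS, filter_travel, fit_clogit, \
    identifiable_covariates, make_steps, predict_suitability, sample_random_steps
from .synthetic import CommunityParams, LandscapeConfig, generate_landscape, \
    simulate_detections, simulate_ssf_track

__all__ = ["ScenarioConfig", "RunManifest", "run_scenarios", "validate_io",
           "TABLE_SSF_ALL"]

#: generating truth for the simulated individuals: the best-supported
#: SSF-All coefficient vectors of the three collared species (puma, ocelot,
#: and three white-lipped peccaries; WLP1/3 reuse plausible per-individual
#: variants of the WLP profile)
TABLE_SSF_ALL: dict[str, dict[str, float]] = {
    "puma": {"elevation": -0.26, "loss": 0.47, "FCOV": 0.10, "DWPA": 1.22},
    "ocelot": {"FCOV": 0.62, "village": -0.14, "loss": 0.03, "DWPA": -0.32,
               "elevation": -0.02, "road": -0.01},
    "WLP1": {"road": -0.13, "elevation": 0.63, "loss": 0.03, "FCOV": -0.06,
             "village": 0.09},
    "WLP2": {"DWPA": 1.15, "FCOV": 0.44, "loss": 0.17},
    "WLP3": {"elevation": 0.60, "DWPA": -0.46, "FCOV": 0.20, "loss": 0.08,
             "village": 0.20},
}

_SPECIES_OF = {"puma": "puma", "ocelot": "ocelot", "WLP1": "white_lipped_peccary",
               "WLP2": "white_lipped_peccary", "WLP3": "white_lipped_peccary"}


@dataclass
class ScenarioConfig:
    """Everything a reproducible scenario run needs."""

    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    groups: dict = field(default_factory=lambda: {
        "sensitive": {"species": ["sp00", "sp01", "sp02"],
                      "individuals": ["WLP1", "WLP2", "WLP3"],
                      "barrier_fraction": 0.95},
        "tolerant": {"species": ["sp03", "sp04", "sp05", "sp06", "sp07", "sp08"],
                     "individuals": ["puma", "ocelot"],
                     "barrier_fraction": 0.85},
    })
    sources: list[str] = field(default_factory=lambda: ["occupancy", "SSF-All",
                                                        "SSF-Travel"])
    curves: list[str] = field(default_factory=lambda: ["linear", "exp_c3", "exp_c8"])
    cutoff: float = 25000.0
    min_core_area_km2: float = 0.5
    n_sites: int = 200
    n_occasions: int = 6
    mcmc: dict = field(default_factory=lambda: {"chains": 2, "iterations": 4000,
                                                "burn_in": 2000, "thin": 5})
    n_track_steps: int = 350
    K: int = 100
    ssf_kinetics: tuple[float, float] = (1.5, 300.0)
    use_threshold_rule: bool = True

    def __post_init__(self) -> None:
        if not (self.groups and self.sources and self.curves):
            raise ValueError("groups, sources and curves must be non-empty")
        for g, spec in self.groups.items():
            f = spec.get("barrier_fraction", 1.0)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"barrier fraction for {g!r} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "landscape" in raw:
            raw["landscape"] = LandscapeConfig(**raw["landscape"])
        if "ssf_kinetics" in raw:
            raw["ssf_kinetics"] = tuple(raw["ssf_kinetics"])
        return cls(**raw)

    def to_yaml_str(self) -> str:
        d = {
            "seed": self.seed,
            "landscape": vars(self.landscape),
            "groups": self.groups, "sources": self.sources,
            "curves": self.curves, "cutoff": self.cutoff,
            "min_core_area_km2": self.min_core_area_km2,
            "n_sites": self.n_sites, "n_occasions": self.n_occasions,
            "mcmc": self.mcmc, "n_track_steps": self.n_track_steps,
            "K": self.K, "ssf_kinetics": list(self.ssf_kinetics),
            "use_threshold_rule": self.use_threshold_rule,
        }
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class RunManifest:
    config_hash: str = ""
    version: str = ""
    files: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    scenarios: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"config_hash": self.config_hash, "version": self.version,
                 "files": self.files, "warnings": self.warnings,
                 "timings": self.timings, "scenarios": self.scenarios}, fh)


def _stage_seeds(root: int) -> dict[str, int]:
    names = ["landscape", "detections", "occupancy", "puma", "ocelot",
             "WLP1", "WLP2", "WLP3", "controls"]
    children = np.random.SeedSequence(root).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _default_community(covariates: list[str]) -> CommunityParams:
    """Community truth: sensitive species (first three) lean on forest and
    protected-area depth; tolerant species respond more weakly."""
    mu = {"road": 0.1, "village": -0.2, "elevation": 0.2, "FCOV": 0.8,
          "DWPA": 0.6, "loss": -0.3}
    return CommunityParams(
        covariates=covariates,
        mu=np.array([mu.get(c, 0.0) for c in covariates]),
        sigma=np.full(len(covariates), 0.5),
        intercept_mu=-0.2, intercept_sd=0.8,
        p_mu=0.0, p_sd=0.5, n_species=9,
    )


def run_scenarios(config: ScenarioConfig, outdir: str | Path) -> RunManifest:
    """Run the full scenario matrix; artifacts land under ``outdir``.

    One resistance surface (.asc) per group x source x curve, plus per-
    scenario corridor products and a YAML manifest (written even on
    failure).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config.to_yaml_str().encode()).hexdigest()[:16],
        version=__version__,
    )
    t0 = time.time()
    try:
        _run(config, outdir, manifest)
    finally:
        manifest.timings["total"] = time.time() - t0
        manifest.write(outdir / "manifest.yaml")
        manifest.files.append(str(outdir / "manifest.yaml"))
    return manifest


def _run(config: ScenarioConfig, outdir: Path, manifest: RunManifest) -> None:
    seeds = _stage_seeds(config.seed)
    tic = time.time()
    land_cfg = LandscapeConfig(**{**vars(config.landscape), "seed": seeds["landscape"]})
    stack = generate_landscape(land_cfg)
    prepared = standardize_stack(stack)
    screen_collinearity(prepared)
    stack_dir = outdir / "stack"
    for p in prepared.stack.write_dir(stack_dir):
        manifest.files.append(str(p))
    manifest.timings["landscape"] = time.time() - tic

    # ---- occupancy branch: all covariates but forest loss
    tic = time.time()
    occ_covs = [c for c in prepared.retained if c != "loss"]
    params = _default_community(occ_covs)
    hist, _truth = simulate_detections(stack, params, config.n_sites,
                                       config.n_occasions, seeds["detections"])
    hist.to_csv(outdir / "detections.csv", outdir / "sites.csv")
    manifest.files += [str(outdir / "detections.csv"), str(outdir / "sites.csv")]
    post = fit_community_occupancy(
        hist, OccupancyModelSpec(occ_covs), seed=seeds["occupancy"], **config.mcmc
    )
    manifest.warnings += post.warnings
    psi = predict_psi(post, prepared)
    manifest.timings["occupancy"] = time.time() - tic

    # ---- SSF branch: simulate collared individuals, fit per individual/mode
    tic = time.time()
    grid = stack.grid
    center = grid.cell_center(grid.shape[0] // 2, grid.shape[1] // 2)
    ssf_suit: dict[tuple[str, str], Raster] = {}
    model_rows = []
    for ind, beta in TABLE_SSF_ALL.items():
        track = simulate_ssf_track(stack, beta, config.ssf_kinetics,
                                   config.n_track_steps, center,
                                   seed=seeds[ind], individual_id=ind)
        track.to_csv(outdir / f"track_{ind}.csv")
        manifest.files.append(str(outdir / f"track_{ind}.csv"))
        observed = make_steps(track)
        stepset = sample_random_steps(observed, prepared, K=config.K,
                                      seed=seeds["controls"],
                                      covariates=list(beta),
                                      individual_id=ind)
        for mode in ("All", "Travel"):
            ss = stepset
            if mode == "Travel":
                ss = filter_travel(stepset, TRAVEL_THRESHOLDS[_SPECIES_OF[ind]])
            covs = identifiable_covariates(ss, ss.covariates)
            if set(covs) != set(ss.covariates):
                dropped = sorted(set(ss.covariates) - set(covs))
                manifest.warnings.append(
                    f"{ind}/{mode}: covariates {dropped} constant within every "
                    "stratum; dropped")
            model = fit_clogit(ss, covs)
            ssf_suit[(ind, f"SSF-{mode}")] = predict_suitability(model, prepared)
            for name in model.covariates:
                model_rows.append({"individual": ind, "mode": mode,
                                   "covariate": name,
                                   "coef": model.beta[name], "se": model.se[name],
                                   "AICc": model.aicc, "n_strata": model.n_strata})
    pd.DataFrame(model_rows).to_csv(outdir / "ssf_models.csv", index=False)
    manifest.files.append(str(outdir / "ssf_models.csv"))
    manifest.timings["ssf"] = time.time() - tic

    # ---- cores per group from group-mean occupancy
    tic = time.time()
    barrier = grid.like(
        (stack.aux["road_mask"]).astype(float)
    )
    barrier.write_ascii(outdir / "barrier.asc")
    manifest.files.append(str(outdir / "barrier.asc"))
    cores_by_group = {}
    group_psi = {}
    for g, gspec in config.groups.items():
        members = [psi[sp] for sp in gspec["species"]]
        mean_psi = grid.like(np.nanmean(np.stack([m.data for m in members]), axis=0))
        group_psi[g] = mean_psi
        if config.use_threshold_rule:
            thr, curve = occupancy_area_threshold(mean_psi)
            curve.to_csv(outdir / f"occupancy_area_{g}.csv", index=False)
            manifest.files.append(str(outdir / f"occupancy_area_{g}.csv"))
        else:
            thr = GROUP_DEFAULT_THRESHOLDS[g]
        thr = min(max(thr, 0.01), 0.99)
        cores = extract_cores(mean_psi, thr, config.min_core_area_km2)
        cores_by_group[g] = cores
        cores.labels.write_ascii(outdir / f"cores_{g}.asc")
        manifest.files.append(str(outdir / f"cores_{g}.asc"))
    manifest.timings["cores"] = time.time() - tic

    # ---- resistance matrix + corridors
    tic = time.time()
    for g, gspec in config.groups.items():
        for source in config.sources:
            if source == "occupancy":
                members = {sp: psi[sp] for sp in gspec["species"]}
            else:
                members = {ind: ssf_suit[(ind, source)]
                           for ind in gspec["individuals"]}
            for curve_name in config.curves:
                scen = {"group": g, "source": source, "curve": curve_name}
                try:
                    curve = CURVES[curve_name]
                    layers = [
                        ResistanceSurface(transform(hs, curve), g, source,
                                          curve_name, member)
                        for member, hs in members.items()
                    ]
                    combined = combine_group(layers, g, source, curve_name)
                    raw_name = outdir / f"combined_{g}_{source}_{curve_name}.asc"
                    combined.raster.write_ascii(raw_name)
                    manifest.files.append(str(raw_name))
                    combined = burn_barriers(combined, barrier,
                                             gspec["barrier_fraction"])
                    fname = outdir / f"resistance_{g}_{source}_{curve_name}.asc"
                    combined.raster.write_ascii(fname)
                    manifest.files.append(str(fname))
                    results, table = connect_cores(combined, cores_by_group[g],
                                                   cutoff=config.cutoff)
                    table.to_csv(outdir / f"pairs_{g}_{source}_{curve_name}.csv",
                                 index=False)
                    manifest.files.append(
                        str(outdir / f"pairs_{g}_{source}_{curve_name}.csv"))
                    scen.update(status="ok", n_corridors=len(results),
                                resistance_file=str(fname))
                except Exception as exc:
                    scen.update(status=f"failed: {exc}")
                    manifest.warnings.append(
                        f"scenario {g}/{source}/{curve_name} failed: {exc}")
                manifest.scenarios.append(scen)
    manifest.timings["resistance_corridors"] = time.time() - tic


# --------------------------------------------------------------------- checks
def validate_io(paths: dict) -> dict:
    """Machine-readable congruence/schema report for run inputs.

    ``paths`` may contain 'rasters' (list of .asc paths), 'detections'
    (CSV path), 'tracks' (list of CSV paths).  Returns
    {'failures': [...], 'checked': n}.
    """
    failures: list[str] = []
    checked = 0
    rasters = [Raster.read_ascii(p) for p in paths.get("rasters", [])]
    if rasters:
        ref = rasters[0]
        for p, r in zip(paths["rasters"], rasters):
            checked += 1
            if not ref.same_grid(r):
                failures.append(f"raster {p}: grid incongruent with {paths['rasters'][0]}")
    if "detections" in paths:
        checked += 1
        det = pd.read_csv(paths["detections"])
        need = {"site", "occasion", "species", "y"}
        if not need.issubset(det.columns):
            failures.append(f"detections: missing columns {need - set(det.columns)}")
        elif not det["y"].isin([0, 1]).all():
            bad = det.loc[~det["y"].isin([0, 1]), "y"].unique()
            failures.append(f"detections: non-binary y values {list(bad)[:5]}")
    for p in paths.get("tracks", []):
        checked += 1
        tr = pd.read_csv(p)
        need = {"individual", "timestamp", "x", "y"}
        if not need.issubset(tr.columns):
            failures.append(f"track {p}: missing columns {need - set(tr.columns)}")
        elif not pd.to_datetime(tr["timestamp"]).is_monotonic_increasing:
            failures.append(f"track {p}: timestamps not increasing")
    return {"failures": failures, "checked": checked}
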