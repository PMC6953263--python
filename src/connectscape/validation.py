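"""Simulation-based validation: coefficient-recovery studies.

These routines close the loop the package is built around: simulate data
from a model with known parameters, fit the model, and measure how well the
generating values are recovered.  They are used both by the test suite and
by reproduction scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import standardize_stack
from .occupancy import OccupancyModelSpec, fit_community_occupancy
from .ssf import LENGTH_ADJUSTMENT, fit_clogit, make_steps, sample_random_steps
from .synthetic import (CommunityParams, LandscapeConfig, generate_landscape,
                        simulate_detections, simulate_ssf_track)

__all__ = ["recover_ssf", "occupancy_coverage", "SSF_TRUTH"]

#: generating coefficient vectors for the three collared-individual recovery
#: studies (the best-supported all-data step-selection models)
SSF_TRUTH: dict[str, dict[str, float]] = {
    "puma": {"elevation": -0.26, "loss": 0.47, "FCOV": 0.10, "DWPA": 1.22},
    "ocelot": {"FCOV": 0.62, "village": -0.14, "loss": 0.03, "DWPA": -0.32,
               "elevation": -0.02, "road": -0.01},
    "WLP2": {"DWPA": 1.15, "FCOV": 0.44, "loss": 0.17},
}


def recover_ssf(
    individual: str,
    seed: int,
    n_steps: int = 3000,
    K: int = 100,
    J: int = 500,
    kinetics: tuple[float, float] = (1.5, 300.0),
    landscape: LandscapeConfig | None = None,
):
    """Simulate a track under a known SSF and refit it.

    A track of ``n_steps`` hourly steps is simulated on a synthetic
    landscape with the generating coefficients of ``individual`` (see
    :data:`SSF_TRUTH`), strata are rebuilt with ``K`` fresh gamma-length
    uniform-angle controls, and the conditional-logistic model is fitted
    with the movement-kernel correction terms.  Returns the fitted model
    and the truth dict.
    """
    truth = SSF_TRUTH[individual]
    landscape = landscape or LandscapeConfig(rows=300, cols=300, seed=seed,
                                             n_villages=20)
    stack = generate_landscape(landscape)
    prepared = standardize_stack(stack)
    grid = stack.grid
    start = grid.cell_center(grid.shape[0] // 2, grid.shape[1] // 2)
    track = simulate_ssf_track(stack, truth, kinetics, n_steps, start,
                               seed=seed + 1, J=J, individual_id=individual)
    observed = make_steps(track)
    stepset = sample_random_steps(observed, prepared, K=K, seed=seed + 2,
                                  covariates=list(truth),
                                  individual_id=individual)
    model = fit_clogit(stepset, list(truth) + LENGTH_ADJUSTMENT)
    return model, truth


def occupancy_coverage(
    seed: int,
    n_replicates: int = 20,
    n_species: int = 10,
    n_sites: int = 500,
    n_occasions: int = 8,
    covariates: list[str] = ("elevation", "FCOV", "DWPA"),
    mcmc: dict | None = None,
) -> pd.DataFrame:
    """Credible-interval coverage of community-model slopes over replicates.

    Each replicate simulates detection histories from the hierarchical
    occupancy model with community means/sds drawn once per replicate, fits
    the model by MCMC, and records whether each generating species slope
    α_in falls inside its central 95% credible interval.  Returns one row
    per (replicate, species, covariate).
    """
    covariates = list(covariates)
    mcmc = mcmc or {"chains": 2, "iterations": 2500, "burn_in": 1000, "thin": 3}
    rows = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(rep_seed)
        land = LandscapeConfig(rows=120, cols=120, seed=rep_seed)
        stack = generate_landscape(land)
        params = CommunityParams(
            covariates=covariates,
            mu=rng.normal(0.0, 0.7, len(covariates)),
            sigma=rng.uniform(0.3, 0.8, len(covariates)),
            intercept_mu=rng.normal(0.0, 0.5),
            intercept_sd=0.8,
            p_mu=0.5, p_sd=0.4,
            n_species=n_species,
        )
        hist, truth = simulate_detections(stack, params, n_sites, n_occasions,
                                          seed=rep_seed + 1)
        post = fit_community_occupancy(hist, OccupancyModelSpec(covariates),
                                       seed=rep_seed + 2, **mcmc)
        draws = post.pooled("coefficients")
        for i in range(n_species):
            for c, name in enumerate(covariates):
                lo, hi = np.percentile(draws[:, i, c + 1], [2.5, 97.5])
                rows.append({
                    "replicate": rep, "species": i, "covariate": name,
                    "truth": truth["slopes"][i, c],
                    "post_mean": draws[:, i, c + 1].mean(),
                    "lo": lo, "hi": hi,
                    "covered": bool(lo <= truth["slopes"][i, c] <= hi),
                })
    return pd.DataFrame(rows)
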