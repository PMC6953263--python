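"""Bayesian hierarchical multi-species occupancy model, occupancy surfaces,
and core-area extraction.

The model: for species i at camera site j with standardized site covariates
V1..Vn,

    logit(Ψ_ij) = α_i + α_i1 V1(j) + ... + α_in Vn(j)
    z_ij ~ Bernoulli(Ψ_ij)                     (latent presence)
    y_ijk ~ Bernoulli(z_ij · p_i)              (occasion k detections)

with species parameters drawn from community-level distributions
α_in ~ Normal(μ_n, σ_n) (the intercept α_i likewise), and a species
detection intercept logit(p_i) ~ Normal(μ_p, σ_p).  Sharing strength across
the community is what lets rare species borrow information from common
ones.  Priors: community means ~ Normal(0, 1.5), community sds ~
half-Normal(1.5).

Inference is Metropolis-within-Gibbs: the latent z_ij have an exact
conjugate Bernoulli update, species coefficients and detection intercepts
move by random-walk Metropolis (step sizes adapted during burn-in only),
community means are conjugate normal draws, and community sds move on the
log scale.  Chains are independent and seeded, so runs are reproducible.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .covariates import PreparedStack
from .raster import Raster
from .synthetic import DetectionHistory

__all__ = [
    "OccupancyModelSpec",
    "CommunityPosterior",
    "CoreAreaSet",
    "NoCoresError",
    "fit_community_occupancy",
    "predict_psi",
    "occupancy_area_threshold",
    "extract_cores",
]


class NoCoresError(RuntimeError):
    """Thresholding produced no core areas; corridors are impossible."""


@dataclass
class OccupancyModelSpec:
    """Covariates and prior hyperparameters of the community model."""

    covariates: list[str]
    mean_prior_sd: float = 1.5
    sd_prior_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.mean_prior_sd <= 0 or self.sd_prior_sd <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class CommunityPosterior:
    """Posterior draws from the community occupancy sampler.

    Array shapes: coefficients (chains, draws, species, 1+P) with column 0
    the intercept; detection (chains, draws, species) on the logit scale;
    community means/sds (chains, draws, 1+P).
    """

    coefficients: np.ndarray
    detection: np.ndarray
    comm_mean: np.ndarray
    comm_sd: np.ndarray
    det_mean: np.ndarray
    det_sd: np.ndarray
    species: list[str]
    covariates: list[str]
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    ess: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_draws(self) -> int:
        return self.coefficients.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws with chains stacked, e.g. pooled('coefficients')."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def coef_summary(self) -> pd.DataFrame:
        draws = self.pooled("coefficients")
        cols = ["intercept"] + self.covariates
        rows = []
        for i, sp in enumerate(self.species):
            for c, name in enumerate(cols):
                d = draws[:, i, c]
                lo, hi = np.percentile(d, [2.5, 97.5])
                rows.append({"species": sp, "parameter": name,
                             "mean": d.mean(), "sd": d.std(),
                             "q2.5": lo, "q97.5": hi})
        return pd.DataFrame(rows)

    def detection_prob(self) -> pd.Series:
        p = special.expit(self.pooled("detection")).mean(axis=0)
        return pd.Series(p, index=self.species, name="p")


def _loglik_z(logits: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-species Bernoulli(z | ilogit(logits)) log-likelihood (sum sites)."""
    return (z * logits - np.logaddexp(0.0, logits)).sum(axis=0)


def fit_community_occupancy(
    Y: DetectionHistory,
    spec: OccupancyModelSpec | None = None,
    chains: int = 3,
    iterations: int = 20000,
    burn_in: int = 10000,
    thin: int = 10,
    seed: int = 0,
) -> CommunityPosterior:
    """Fit the hierarchical multi-species occupancy model by MCMC.

    Requires >= 2 occasions (one occasion cannot separate occupancy from
    detection).  Species never detected anywhere are flagged in
    ``posterior.warnings``; R-hat > 1.1 on any parameter adds a
    non-convergence warning (and a Python warning), never a silent pass.
    """
    spec = spec or OccupancyModelSpec(Y.covariates)
    if Y.n_occasions < 2:
        raise ValueError("need >= 2 occasions to separate occupancy from detection")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    X = Y.sites[spec.covariates].to_numpy(float)
    J, S, K = Y.n_sites, Y.n_species, Y.n_occasions
    P = X.shape[1]
    Xd = np.column_stack([np.ones(J), X])  # J x (1+P)
    ydet = Y.y.sum(axis=2).astype(float)  # J x S
    detected = ydet > 0
    warn_list = [
        f"species {sp!r} never detected; its parameters follow the community prior"
        for i, sp in enumerate(Y.species) if not detected[:, i].any()
    ]

    n_keep = (iterations - burn_in) // thin
    coef_out = np.empty((chains, n_keep, S, 1 + P))
    det_out = np.empty((chains, n_keep, S))
    mu_out = np.empty((chains, n_keep, 1 + P))
    sig_out = np.empty((chains, n_keep, 1 + P))
    mup_out = np.empty((chains, n_keep))
    sigp_out = np.empty((chains, n_keep))

    prior_m = spec.mean_prior_sd
    prior_s = spec.sd_prior_sd
    seeds = np.random.SeedSequence(seed).spawn(chains)
    for ch in range(chains):
        rng = np.random.default_rng(seeds[ch])
        A = 0.1 * rng.standard_normal((S, 1 + P))
        d = 0.1 * rng.standard_normal(S)
        mu = np.zeros(1 + P)
        sig = np.ones(1 + P)
        mu_p, sig_p = 0.0, 1.0
        z = detected.astype(float)
        step_A = np.full((S, 1 + P), 0.3)
        step_d = np.full(S, 0.3)
        step_sig = np.full(1 + P, 0.3)
        step_sigp = 0.3
        acc_A = np.zeros((S, 1 + P))
        acc_d = np.zeros(S)
        kept = 0
        for it in range(iterations):
            logits = Xd @ A.T  # J x S
            # --- latent presence (conjugate; only undetected pairs uncertain)
            psi = special.expit(logits)
            p = special.expit(d)
            q = psi * (1.0 - p[None, :]) ** K
            prob_z = q / (q + (1.0 - psi))
            z = np.where(detected, 1.0, rng.uniform(size=(J, S)) < prob_z)
            # --- species coefficients, coordinate-wise RW-MH across species
            ll = _loglik_z(logits, z)
            for c in range(1 + P):
                prop = A[:, c] + step_A[:, c] * rng.standard_normal(S)
                delta = prop - A[:, c]
                new_logits = logits + Xd[:, c][:, None] * delta[None, :]
                ll_new = _loglik_z(new_logits, z)
                lp = ((prop - mu[c]) ** 2 - (A[:, c] - mu[c]) ** 2) / (-2 * sig[c] ** 2)
                accept = np.log(rng.uniform(size=S)) < (ll_new - ll + lp)
                A[accept, c] = prop[accept]
                logits[:, accept] = new_logits[:, accept]
                ll = np.where(accept, ll_new, ll)
                acc_A[:, c] += accept
            # --- detection intercepts
            s1 = (z * ydet).sum(axis=0)
            s0 = (z * (K - ydet)).sum(axis=0)
            prop_d = d + step_d * rng.standard_normal(S)
            def det_ll(dv):
                return s1 * np.log(special.expit(dv)) + s0 * np.log(special.expit(-dv))
            lp = ((prop_d - mu_p) ** 2 - (d - mu_p) ** 2) / (-2 * sig_p**2)
            accept = np.log(rng.uniform(size=S)) < (det_ll(prop_d) - det_ll(d) + lp)
            d = np.where(accept, prop_d, d)
            acc_d += accept
            # --- community means (conjugate normal)
            prec = S / sig**2 + 1.0 / prior_m**2
            mean = (A.sum(axis=0) / sig**2) / prec
            mu = mean + rng.standard_normal(1 + P) / np.sqrt(prec)
            prec_p = S / sig_p**2 + 1.0 / prior_m**2
            mu_p = d.sum() / sig_p**2 / prec_p + rng.standard_normal() / np.sqrt(prec_p)
            # --- community sds (log-scale RW-MH, half-normal prior)
            for c in range(1 + P):
                ls_new = np.log(sig[c]) + step_sig[c] * rng.standard_normal()
                s_new = np.exp(ls_new)
                res = ((A[:, c] - mu[c]) ** 2).sum()
                def sd_logpost(s):
                    return (-S * np.log(s) - res / (2 * s**2)
                            - s**2 / (2 * prior_s**2) + np.log(s))
                if np.log(rng.uniform()) < sd_logpost(s_new) - sd_logpost(sig[c]):
                    sig[c] = s_new
            ls_new = np.log(sig_p) + step_sigp * rng.standard_normal()
            s_new = np.exp(ls_new)
            res = ((d - mu_p) ** 2).sum()
            def sdp_logpost(s):
                return (-S * np.log(s) - res / (2 * s**2)
                        - s**2 / (2 * prior_s**2) + np.log(s))
            if np.log(rng.uniform()) < sdp_logpost(s_new) - sdp_logpost(sig_p):
                sig_p = s_new
            # --- step-size adaptation, burn-in only
            if it < burn_in and (it + 1) % 50 == 0:
                step_A *= np.exp(np.clip(acc_A / 50 - 0.44, -0.5, 0.5))
                step_d *= np.exp(np.clip(acc_d / 50 - 0.44, -0.5, 0.5))
                acc_A[:] = 0.0
                acc_d[:] = 0.0
            if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
                coef_out[ch, kept] = A
                det_out[ch, kept] = d
                mu_out[ch, kept] = mu
                sig_out[ch, kept] = sig
                mup_out[ch, kept] = mu_p
                sigp_out[ch, kept] = sig_p
                kept += 1

    post = CommunityPosterior(
        coefficients=coef_out, detection=det_out, comm_mean=mu_out,
        comm_sd=sig_out, det_mean=mup_out, det_sd=sigp_out,
        species=list(Y.species), covariates=list(spec.covariates),
        warnings=warn_list,
    )
    _diagnose(post)
    return post


def _diagnose(post: CommunityPosterior) -> None:
    """Attach split-R-hat and effective sample size (via arviz) per parameter."""
    import arviz as az

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        ds = az.from_dict(posterior={
            "coef": post.coefficients, "det": post.detection,
            "mu": post.comm_mean, "sigma": post.comm_sd,
        })
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    for name in ("coef", "det", "mu", "sigma"):
        post.rhat[name] = np.asarray(rhat[name])
        post.ess[name] = np.asarray(ess[name])
    worst = max(np.nanmax(v) for v in post.rhat.values())
    if worst > 1.1:
        msg = f"MCMC non-convergence: max R-hat = {worst:.3f} > 1.1"
        post.warnings.append(msg)
        _warnings.warn(msg, stacklevel=3)


# --------------------------------------------------------------- prediction
def predict_psi(
    post: CommunityPosterior,
    prepared: PreparedStack,
    species: list[str] | None = None,
    max_draws: int = 400,
    chunk: int = 20000,
) -> dict[str, Raster]:
    """Posterior-mean occupancy surface Ψ per species.

    Averages ilogit(α_i + Σ α_in V_n) over (thinned) posterior draws cell by
    cell; nodata propagates from the covariate stack.
    """
    species = species or post.species
    missing = [c for c in post.covariates if c not in prepared.stack]
    if missing:
        raise ValueError(f"stack lacks model covariates: {missing}")
    grid = prepared.stack.grid
    valid = prepared.stack.valid_mask()
    idx = np.flatnonzero(valid.ravel())
    Xv = np.column_stack(
        [prepared.stack[c].data.ravel()[idx] for c in post.covariates]
    )
    draws = post.pooled("coefficients")
    if draws.shape[0] > max_draws:
        sel = np.linspace(0, draws.shape[0] - 1, max_draws).astype(int)
        draws = draws[sel]
    out: dict[str, Raster] = {}
    for sp in species:
        i = post.species.index(sp)
        a = draws[:, i, 0]
        B = draws[:, i, 1:]
        psi = np.empty(idx.size)
        for lo in range(0, idx.size, chunk):
            hi = min(lo + chunk, idx.size)
            logits = a[None, :] + Xv[lo:hi] @ B.T
            psi[lo:hi] = special.expit(logits).mean(axis=1)
        surf = np.full(grid.shape[0] * grid.shape[1], np.nan)
        surf[idx] = psi
        out[sp] = grid.like(surf.reshape(grid.shape))
    return out


def occupancy_area_threshold(psi: Raster, delta: float = 0.01):
    """Max-slope threshold of the occupancy–area curve.

    A(t) is the fraction of valid cells with Ψ >= t on a regular t grid;
    the returned threshold t* is the (smallest) t maximizing the finite-
    difference slope |A(t+δ) − A(t)| / δ.  Also returns the curve for
    plotting.
    """
    vals = psi.data[psi.valid]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("constant (or empty) occupancy raster: no slope")
    t = np.round(np.arange(0.0, 1.0 + delta / 2, delta), 10)
    area = np.array([(vals >= ti).mean() for ti in t])
    slope = np.abs(np.diff(area)) / delta
    best = int(np.argmax(slope))  # argmax takes the first (smallest t) on ties
    curve = pd.DataFrame({"threshold": t, "area_fraction": area})
    return float(t[best]), curve


#: thresholds the original analysis settled on when the curve step is skipped
GROUP_DEFAULT_THRESHOLDS = {"tolerant": 0.2, "sensitive": 0.3}


@dataclass
class CoreAreaSet:
    """Connected high-occupancy patches (the nodes corridors connect)."""

    labels: Raster  # integer labels, 0 = background, NaN respected as 0
    table: pd.DataFrame  # label, n_cells, area_km2
    threshold: float

    @property
    def n_cores(self) -> int:
        return len(self.table)

    def cells(self, label: int) -> np.ndarray:
        """(row, col) array of the cells of one core."""
        return np.argwhere(self.labels.data == label)

    def to_geojson(self, path) -> None:
        import json

        from shapely import box, to_geojson, union_all

        feats = []
        g = self.labels
        half = g.cell_size / 2
        for label in self.table["label"]:
            cells = self.cells(int(label))
            boxes = [box(cx - half, cy - half, cx + half, cy + half)
                     for r, c in cells
                     for cx, cy in [g.cell_center(int(r), int(c))]]
            geom = union_all(boxes)
            feats.append({
                "type": "Feature",
                "properties": {"label": int(label),
                               "area_km2": float(self.table.set_index("label")
                                                 .loc[int(label), "area_km2"])},
                "geometry": json.loads(to_geojson(geom)),
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def extract_cores(psi: Raster, threshold: float, min_area_km2: float = 0.0) -> CoreAreaSet:
    """8-connected components of {Ψ >= threshold}, small patches dropped.

    Labels follow row-major discovery order.  Raises :class:`NoCoresError`
    when nothing survives.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = np.nan_to_num(psi.data, nan=-np.inf) >= threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    cell_km2 = (psi.cell_size / 1000.0) ** 2
    rows = []
    out = np.zeros_like(labels)
    new_label = 0
    for lab in range(1, n + 1):
        n_cells = int((labels == lab).sum())
        area = n_cells * cell_km2
        if area < min_area_km2:
            continue
        new_label += 1
        out[labels == lab] = new_label
        rows.append({"label": new_label, "n_cells": n_cells, "area_km2": area})
    if not rows:
        raise NoCoresError(
            f"no core areas at threshold {threshold} (min area {min_area_km2} km^2)"
        )
    return CoreAreaSet(psi.like(out.astype(float)), pd.DataFrame(rows), threshold)
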