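"""Step-selection functions: strata construction, conditional-logit fitting,
AICc model selection, and movement-suitability prediction.

A step is the straight line between two consecutive hourly GPS fixes.  Each
observed step is matched with K control steps (default 100) sharing its
start point, with lengths drawn from a gamma distribution fitted by maximum
likelihood to the observed step lengths and turn angles drawn uniformly.
Used habitat is compared with available habitat through the conditional
logistic likelihood

    l(β) = Σ_strata [ β'x_obs − log Σ_steps exp(β'x) ],

maximized by Newton iteration with analytic gradient and Hessian.  The
"Travel" mode keeps only strata whose observed step exceeds a
species-specific length threshold (ocelot 100 m, white-lipped peccary
150 m, puma 200 m), a proxy for directed movement; turn angle is
deliberately not used to classify behavior.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import PreparedStack, aicc
from .synthetic import Track

__all__ = [
    "TRAVEL_THRESHOLDS",
    "LENGTH_ADJUSTMENT",
    "make_steps",
    "sample_random_steps",
    "filter_travel",
    "fit_clogit",
    "aicc_select",
    "predict_suitability",
    "StepSet",
    "SSFModel",
    "SeparationError",
]

#: species-specific minimum observed step length (m) defining travel mode
TRAVEL_THRESHOLDS = {"ocelot": 100.0, "white_lipped_peccary": 150.0, "puma": 200.0}

#: movement-kernel correction terms added by sample_random_steps
LENGTH_ADJUSTMENT = ["sl", "log_sl"]


class SeparationError(RuntimeError):
    """Conditional-logit MLE diverged (complete separation)."""


# --------------------------------------------------------------------- steps
def make_steps(track: Track, interval: float = 3600.0,
               tolerance: float = 300.0) -> pd.DataFrame:
    """Observed steps from consecutive fixes spaced interval ± tolerance.

    Returns a DataFrame (stratum, x_start, y_start, x_end, y_end, length,
    turn_angle); the turn angle is relative to the previous retained step
    and NaN when that step is missing or non-contiguous.
    """
    fixes = track.fixes
    if len(fixes) < 2:
        raise ValueError("need at least two fixes")
    t = pd.to_datetime(fixes["timestamp"]).astype("int64").to_numpy() / 1e9
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    rows = []
    prev_bearing = np.nan
    prev_end_idx = -1
    for i in range(len(fixes) - 1):
        dt = t[i + 1] - t[i]
        if abs(dt - interval) > tolerance:
            continue
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        length = float(np.hypot(dx, dy))
        bearing = float(np.arctan2(dy, dx))
        if prev_end_idx == i and np.isfinite(prev_bearing):
            turn = (bearing - prev_bearing + np.pi) % (2 * np.pi) - np.pi
        else:
            turn = np.nan
        rows.append((len(rows), x[i], y[i], x[i + 1], y[i + 1], length, turn))
        prev_bearing = bearing
        prev_end_idx = i + 1
    if not rows:
        raise ValueError("no valid steps at the requested interval")
    return pd.DataFrame(
        rows,
        columns=["stratum", "x_start", "y_start", "x_end", "y_end", "length",
                 "turn_angle"],
    )


@dataclass
class StepSet:
    """Strata of one observed + K control steps with end-point covariates."""

    steps: pd.DataFrame  # stratum, case, x_start.., length, covariates...
    covariates: list[str]
    individual_id: str = "ind0"
    mode: str = "All"
    K: int = 100
    gamma_params: tuple[float, float] = (np.nan, np.nan)  # (shape, scale)
    n_dropped_strata: int = 0
    n_excluded_controls: int = 0

    @property
    def n_strata(self) -> int:
        return self.steps["stratum"].nunique()

    def observed(self) -> pd.DataFrame:
        return self.steps[self.steps["case"] == 1]

    def to_csv(self, path: str | Path) -> None:
        self.steps.to_csv(path, index=False)


def sample_random_steps(
    observed: pd.DataFrame,
    prepared: PreparedStack,
    K: int = 100,
    seed: int = 0,
    covariates: list[str] | None = None,
    individual_id: str = "ind0",
    max_invalid_fraction: float = 0.10,
) -> StepSet:
    """Pair each observed step with K gamma-length, uniform-angle controls.

    The gamma is fitted by MLE (location fixed at 0) to this individual's
    observed lengths.  Controls share the observed step's start point.
    Controls landing outside the extent or on nodata are excluded from the
    stratum; strata whose observed end point is invalid or with more than
    ``max_invalid_fraction`` invalid controls are dropped entirely.

    Because the gamma is fitted to *selected* lengths it is only a tentative
    availability kernel; the step set therefore carries derived columns
    ``sl`` (length, km) and ``log_sl`` whose inclusion in the conditional
    logit corrects the kernel (the movement terms span any gamma
    reweighting).  Use ``covariates + LENGTH_ADJUSTMENT`` when fitting for
    unbiased habitat coefficients; see :data:`LENGTH_ADJUSTMENT`.
    """
    covariates = covariates or prepared.retained
    if len(observed) < 5:
        raise ValueError("need at least 5 observed steps to fit the gamma")
    lengths = observed["length"].to_numpy(float)
    lengths = lengths[lengths > 0]
    if np.ptp(lengths) == 0:
        raise ValueError("degenerate step lengths: gamma fit impossible")
    shape_k, _, scale_k = stats.gamma.fit(lengths, floc=0)
    rng = np.random.default_rng(seed)
    stack = prepared.stack

    frames = []
    n_dropped = 0
    n_excluded = 0
    for stratum_out, (_, obs) in enumerate(observed.iterrows()):
        obs_cov = stack.values_at([obs.x_end], [obs.y_end], covariates)[0]
        if np.isnan(obs_cov).any():
            n_dropped += 1
            continue
        ln = rng.gamma(shape_k, scale_k, size=K)
        ang = rng.uniform(-np.pi, np.pi, size=K)
        ex = obs.x_start + ln * np.cos(ang)
        ey = obs.y_start + ln * np.sin(ang)
        cov = stack.values_at(ex, ey, covariates)
        ok = ~np.isnan(cov).any(axis=1)
        if (~ok).sum() > max_invalid_fraction * K:
            n_dropped += 1
            continue
        n_excluded += int((~ok).sum())
        n_ok = int(ok.sum())
        df = pd.DataFrame({
            "stratum": stratum_out,
            "case": np.concatenate([[1], np.zeros(n_ok, dtype=int)]),
            "x_start": obs.x_start, "y_start": obs.y_start,
            "x_end": np.concatenate([[obs.x_end], ex[ok]]),
            "y_end": np.concatenate([[obs.y_end], ey[ok]]),
            "length": np.concatenate([[obs.length], ln[ok]]),
        })
        allcov = np.vstack([obs_cov, cov[ok]])
        for k, name in enumerate(covariates):
            df[name] = allcov[:, k]
        df["sl"] = df["length"] / 1000.0
        df["log_sl"] = np.log(np.maximum(df["length"], 1e-6))
        frames.append(df)
    if not frames:
        raise ValueError("all strata dropped while sampling controls")
    steps = pd.concat(frames, ignore_index=True)
    # renumber strata densely
    steps["stratum"] = pd.factorize(steps["stratum"])[0]
    return StepSet(steps, list(covariates), individual_id, "All", K,
                   (float(shape_k), float(scale_k)), n_dropped, n_excluded)


def filter_travel(stepset: StepSet, min_length: float) -> StepSet:
    """Keep only strata whose observed step length >= min_length (travel mode)."""
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    obs = stepset.observed()
    keep = set(obs.loc[obs["length"] >= min_length, "stratum"])
    if not keep:
        raise ValueError("travel filter removed every stratum")
    steps = stepset.steps[stepset.steps["stratum"].isin(keep)].copy()
    steps["stratum"] = pd.factorize(steps["stratum"])[0]
    return StepSet(steps, stepset.covariates, stepset.individual_id, "Travel",
                   stepset.K, stepset.gamma_params,
                   stepset.n_dropped_strata, stepset.n_excluded_controls)


# --------------------------------------------------------------------- fitting
@dataclass
class SSFModel:
    """A fitted conditional-logistic step-selection model."""

    beta: pd.Series
    se: pd.Series
    vcov: np.ndarray
    loglik: float
    aicc: float
    n_strata: int
    covariates: list[str]
    individual_id: str = "ind0"
    mode: str = "All"
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.beta, "se": self.se,
                             "z": self.beta / self.se})


def _clogit_parts(stepset: StepSet, covariates: list[str]):
    df = stepset.steps.sort_values(["stratum", "case"],
                                   ascending=[True, False], kind="stable")
    X = df[covariates].to_numpy(float)
    strata = df["stratum"].to_numpy()
    starts = np.flatnonzero(np.r_[True, strata[1:] != strata[:-1]])
    case = df["case"].to_numpy() == 1
    if not (case[starts].all() and case.sum() == starts.size):
        raise ValueError("each stratum must contain exactly one observed step")
    return X, starts, case


def _clogit_loglik(beta: np.ndarray, X: np.ndarray, starts: np.ndarray,
                   case: np.ndarray):
    """(loglik, gradient, hessian) of the conditional-logistic likelihood."""
    s = X @ beta
    smax = np.maximum.reduceat(s, starts)
    grp = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, s.size]))
    e = np.exp(s - smax[grp])
    denom = np.add.reduceat(e, starts)
    w = e / denom[grp]  # within-stratum softmax
    ll = float(s[case].sum() - (np.log(denom) + smax).sum())
    xbar = np.empty((starts.size, X.shape[1]))
    for k in range(X.shape[1]):
        xbar[:, k] = np.add.reduceat(w * X[:, k], starts)
    grad = X[case].sum(axis=0) - xbar.sum(axis=0)
    Xc = X - xbar[grp]
    H = -(Xc * w[:, None]).T @ Xc
    return ll, grad, H


def identifiable_covariates(stepset: StepSet, covariates: list[str]) -> list[str]:
    """Covariates with any within-stratum variation (fittable in a clogit)."""
    X, starts, _ = _clogit_parts(stepset, covariates)
    grp = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, len(X)]))
    keep = []
    for k, name in enumerate(covariates):
        mean_k = np.add.reduceat(X[:, k], starts) / np.diff(np.r_[starts, len(X)])
        if not np.allclose(X[:, k], mean_k[grp]):
            keep.append(name)
    return keep


def fit_clogit(stepset: StepSet, covariates: list[str] | None = None,
               tol: float = 1e-6, max_iter: int = 100,
               beta_bound: float = 15.0) -> SSFModel:
    """Newton-Raphson MLE of the conditional-logistic model.

    Raises :class:`SeparationError` if any |β| escapes ``beta_bound``
    (complete separation) and ValueError for covariates constant within
    every stratum (unidentifiable).
    """
    covariates = covariates or stepset.covariates
    X, starts, case = _clogit_parts(stepset, covariates)
    grp = np.repeat(np.arange(starts.size), np.diff(np.r_[starts, len(X)]))
    for k, name in enumerate(covariates):
        mean_k = np.add.reduceat(X[:, k], starts) / np.diff(np.r_[starts, len(X)])
        if np.allclose(X[:, k], mean_k[grp]):
            raise ValueError(f"covariate {name!r} is constant within every stratum")
    beta = np.zeros(len(covariates))
    ll, grad, H = _clogit_loglik(beta, X, starts, case)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            step = grad / (np.abs(np.diag(H)).max() + 1e-12)
        # Newton step with halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            new = beta - scale * step
            ll_new, grad_new, H_new = _clogit_loglik(new, X, starts, case)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta, ll, grad, H = new, ll_new, grad_new, H_new
        if np.abs(beta).max() > beta_bound:
            raise SeparationError(
                "coefficient escaped bound; likely complete separation"
            )
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    info = -H
    vcov = np.linalg.inv(info + 1e-12 * np.eye(len(beta)))
    se = np.sqrt(np.diag(vcov))
    n = starts.size
    # AICc sample size = number of strata; undefined for n <= k+1
    model_aicc = aicc(ll, len(covariates), n) if n > len(covariates) + 1 else np.nan
    return SSFModel(
        beta=pd.Series(beta, index=covariates),
        se=pd.Series(se, index=covariates),
        vcov=vcov, loglik=ll, aicc=model_aicc, n_strata=n,
        covariates=list(covariates), individual_id=stepset.individual_id,
        mode=stepset.mode, converged=converged,
    )


def aicc_select(stepset: StepSet, candidate_sets: list[list[str]]):
    """Fit each candidate covariate set and rank by AICc.

    Ties break toward fewer parameters, then listed order.  Candidates whose
    fit fails are recorded in the table with NaN AICc and skipped.
    """
    if not candidate_sets:
        raise ValueError("no candidate models")
    rows, models = [], []
    for idx, cand in enumerate(candidate_sets):
        try:
            m = fit_clogit(stepset, cand)
            rows.append({"order": idx, "covariates": "+".join(cand), "k": len(cand),
                         "loglik": m.loglik, "AICc": m.aicc, "error": ""})
            models.append(m)
        except Exception as exc:  # recorded, not fatal
            rows.append({"order": idx, "covariates": "+".join(cand),
                         "k": len(cand), "loglik": np.nan, "AICc": np.nan,
                         "error": str(exc)})
            models.append(None)
    table = pd.DataFrame(rows)
    ok = table["AICc"].notna()
    if not ok.any():
        raise RuntimeError("every candidate model failed to fit")
    table.loc[ok, "dAICc"] = table.loc[ok, "AICc"] - table.loc[ok, "AICc"].min()
    ranked = table[ok].sort_values(["AICc", "k", "order"], kind="stable")
    best = models[int(ranked.index[0])]
    return best, table


def predict_suitability(model: SSFModel, prepared: PreparedStack):
    """Movement-suitability raster: S = Σ β_n V_n, min-max rescaled to [0,1].

    Movement-kernel terms (sl, log_sl) describe the step-length
    distribution, not habitat, and are excluded from the map.
    """
    stack = prepared.stack
    grid = stack.grid
    habitat = [c for c in model.covariates if c not in LENGTH_ADJUSTMENT]
    missing = [c for c in habitat if c not in stack]
    if missing:
        raise ValueError(f"stack lacks model covariates: {missing}")
    if not habitat:
        raise ValueError("model has no habitat covariates")
    S = np.zeros(grid.shape)
    for name in habitat:
        S = S + model.beta[name] * stack[name].data
    valid = stack.valid_mask()
    S = np.where(valid, S, np.nan)
    vals = S[valid]
    lo, hi = np.min(vals), np.max(vals)
    if hi == lo:
        raise ValueError("constant suitability surface; min-max rescale undefined")
    return grid.like((S - lo) / (hi - lo))


def candidate_subsets(covariates: list[str], max_size: int | None = None):
    """All non-empty covariate subsets (optionally capped in size), listed
    smaller-first so AICc ties resolve toward parsimony."""
    max_size = max_size or len(covariates)
    out = []
    for r in range(1, max_size + 1):
        out.extend(list(c) for c in itertools.combinations(covariates, r))
    return out
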