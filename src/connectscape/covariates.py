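"""Multi-scale covariate derivation, standardization and screening.

Habitat covariates enter the suitability models at a characteristic scale:
forest cover and forest loss as the fraction of qualifying pixels inside a
circular moving window, settlement pressure as a point density, road
influence as a Euclidean distance.  Scales are chosen per variable by a
univariate fit ranked with the small-sample Akaike criterion (AICc), the
winners are combined into one multi-scale stack, covariates are centered
and scaled, and pairs with Spearman |rho| above 0.6 are screened out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .raster import CovariateStack, Raster

__all__ = [
    "focal_fraction",
    "distance_transform",
    "point_density",
    "standardize_stack",
    "screen_collinearity",
    "aicc",
    "select_scale",
    "PreparedStack",
    "ScaleCandidateSet",
    "DEFAULT_SCALE_CANDIDATES",
]


def _disc_kernel(radius_cells: float) -> np.ndarray:
    """Boolean circular window: cells whose center lies within the radius."""
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_cells**2


def focal_fraction(binary: Raster, radius: float) -> Raster:
    """Fraction of true cells within a circular window of ``radius`` meters.

    Nodata cells are excluded from both numerator and denominator; a cell
    whose window contains no valid cells is nodata in the output.
    ``radius=0`` (or any radius below one cell) degenerates to the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    vals = binary.data
    valid = binary.valid
    if radius < binary.cell_size:
        return binary.like(vals.astype(float))
    kernel = _disc_kernel(radius / binary.cell_size).astype(float)
    num = signal.fftconvolve(np.where(valid, vals, 0.0), kernel, mode="same")
    den = signal.fftconvolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0.5, num / np.maximum(den, 1e-12), np.nan)
    return binary.like(np.clip(frac, 0.0, 1.0))


def distance_transform(mask: Raster) -> Raster:
    """Euclidean distance in meters to the nearest true cell (0 on true cells)."""
    m = np.nan_to_num(mask.data, nan=0.0) > 0.5
    if not m.any():
        raise ValueError("distance_transform: mask has no true cell")
    dist = ndimage.distance_transform_edt(~m, sampling=mask.cell_size)
    return mask.like(dist)


def point_density(
    points: np.ndarray, radius: float, grid: Raster
) -> Raster:
    """Count of points within ``radius`` m of each cell center, per km^2.

    ``points`` is an (n, 2) array of x/y coordinates; an empty list yields a
    zero raster.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    counts = np.zeros(grid.shape)
    if len(points):
        X, Y = grid.cell_centers()
        for px, py in points:
            counts += (X - px) ** 2 + (Y - py) ** 2 <= radius**2
    area_km2 = np.pi * (radius / 1000.0) ** 2
    return grid.like(counts / area_km2)


# --------------------------------------------------------------------- scaling
@dataclass
class PreparedStack:
    """Covariate stack after standardization (and optionally screening)."""

    stack: CovariateStack
    means: dict[str, float]
    sds: dict[str, float]
    retained: list[str] = field(default_factory=list)
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained:
            self.retained = self.stack.names

    def destandardize(self, name: str, values: np.ndarray) -> np.ndarray:
        return values * self.sds[name] + self.means[name]

    def standardize_values(self, name: str, values: np.ndarray) -> np.ndarray:
        return (values - self.means[name]) / self.sds[name]


def standardize_stack(stack: CovariateStack) -> PreparedStack:
    """Center and scale every layer over its valid cells (z-scores)."""
    layers, means, sds = {}, {}, {}
    for name in stack.names:
        r = stack[name]
        vals = r.data[r.valid]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise ValueError(f"layer {name!r} is constant; cannot standardize")
        layers[name] = r.like((r.data - mu) / sd)
        means[name], sds[name] = mu, sd
    return PreparedStack(CovariateStack(layers, aux=stack.aux), means, sds)


def screen_collinearity(
    prepared: PreparedStack, rho_max: float = 0.6, max_cells: int = 20000, seed: int = 0
) -> list[str]:
    """Greedy Spearman screen: drop layers until all pairwise |rho| <= rho_max.

    At each round the layer with the largest mean absolute correlation to
    all remaining layers among the offending pairs is removed.  Dropped
    pairs are logged on the PreparedStack.
    """
    names = list(prepared.retained)
    if len(names) < 2:
        raise ValueError("need at least two layers to screen")
    stack = prepared.stack
    mask = stack.valid_mask()
    idx = np.flatnonzero(mask.ravel())
    if idx.size > max_cells:
        idx = np.random.default_rng(seed).choice(idx, max_cells, replace=False)
    mat = np.column_stack([stack[n].data.ravel()[idx] for n in names])
    for j, n in enumerate(names):
        if np.ptp(mat[:, j]) == 0:
            raise ValueError(f"layer {n!r} is constant; Spearman undefined")
    p = len(names)
    rho = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            r = stats.spearmanr(mat[:, a], mat[:, b]).statistic
            rho[a, b] = rho[b, a] = r
    keep = list(range(len(names)))
    while True:
        sub = np.abs(rho[np.ix_(keep, keep)])
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= rho_max:
            break
        mean_abs = sub.mean(axis=1)
        # restrict removal to layers involved in an offending pair
        offenders = np.unique(np.argwhere(sub > rho_max))
        worst_local = offenders[np.argmax(mean_abs[offenders])]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        prepared.dropped_pairs.append(
            (names[keep[i]], names[keep[j]], float(rho[keep[i], keep[j]]))
        )
        keep.pop(int(worst_local))
    retained = [names[k] for k in keep]
    prepared.retained = retained
    return retained


@dataclass
class ScaleCandidateSet:
    """Candidate characteristic scales for one multi-scale variable.

    Defaults follow the standard design: settlement density at 2/5/10/20 km,
    forest loss and forest cover at 150 m/500 m/1 km/2 km, the latter
    crossed with tree-cover thresholds of 50/75/90%.
    """

    variable: str
    radii: tuple[float, ...]
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if (r <= 0).any() or (np.diff(r) <= 0).any():
            raise ValueError("radii must be positive and strictly increasing")
        if any(not 0 < t <= 100 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 100]")

    def candidates(self) -> list:
        """Radii, or (radius, threshold) pairs when thresholds are set."""
        if not self.thresholds:
            return list(self.radii)
        return [(r, t) for r in self.radii for t in self.thresholds]


#: the standard candidate sets for the three multi-scale variables
DEFAULT_SCALE_CANDIDATES = {
    "village": ScaleCandidateSet("village", (2000.0, 5000.0, 10000.0, 20000.0)),
    "loss": ScaleCandidateSet("loss", (150.0, 500.0, 1000.0, 2000.0)),
    "FCOV": ScaleCandidateSet("FCOV", (150.0, 500.0, 1000.0, 2000.0),
                              (50.0, 75.0, 90.0)),
}


# --------------------------------------------------------------------- AICc
def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_scale(candidates, fit) -> tuple:
    """Pick the candidate scale minimizing AICc for a univariate fit.

    Parameters
    ----------
    candidates
        Sequence of candidate descriptors (e.g. radii in meters, or
        (radius, threshold) tuples for forest cover).
    fit
        Callable ``fit(candidate) -> (loglik, k, n)``.

    Returns
    -------
    (best_candidate, table)
        ``table`` is a DataFrame with candidate, loglik, k, n, AICc and
        delta-AICc, sorted by AICc.  Ties break toward the earlier (smaller)
        candidate.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates")
    rows = []
    for cand in candidates:
        ll, k, n = fit(cand)
        rows.append({"candidate": cand, "loglik": ll, "k": k, "n": n,
                     "AICc": aicc(ll, k, n)})
    table = pd.DataFrame(rows)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    # stable sort keeps listed (ascending-radius) order on ties
    order = table["AICc"].values
    best = candidates[int(np.argmin(order))]
    return best, table.sort_values("AICc", kind="stable").reset_index(drop=True)
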