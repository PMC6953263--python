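"""Suitability-to-resistance transformation and group-level combination.

Resistance is the negative inverse of habitat suitability HS in [0, 1].
Three curves are supported:

    linear        R = 100 − 100·HS                      (range [0, 100])
    exponential   R = 100 − 99·(1 − e^{−c·HS})/(1 − e^{−c})   (range [1, 100])

with shape factor c = 3 or c = 8; larger c keeps resistance low until
suitability is very poor, reflecting animals moving readily through
moderately unsuitable habitat when dispersing.  Per-species (occupancy) or
per-individual (SSF) resistance layers are z-scored over valid cells,
averaged cellwise, and min-max rescaled so each group surface spans exactly
[1, 1000] (1 = lowest cost).  Roads and urban cells are then burned in at a
fraction of the pre-burn surface maximum (0.85 tolerant, 0.95 sensitive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Raster

__all__ = [
    "TransformationCurve",
    "ResistanceSurface",
    "transform",
    "combine_group",
    "burn_barriers",
    "CURVES",
]


@dataclass(frozen=True)
class TransformationCurve:
    kind: str  # "linear" | "exponential"
    c: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "exponential"):
            raise ValueError("kind must be 'linear' or 'exponential'")
        if self.kind == "exponential" and (self.c is None or self.c <= 0):
            raise ValueError("exponential curve needs c > 0")

    @property
    def name(self) -> str:
        return "linear" if self.kind == "linear" else f"exp_c{self.c:g}"


#: the standard three-curve set
CURVES = {
    "linear": TransformationCurve("linear"),
    "exp_c3": TransformationCurve("exponential", 3.0),
    "exp_c8": TransformationCurve("exponential", 8.0),
}


@dataclass
class ResistanceSurface:
    """Resistance raster with provenance."""

    raster: Raster
    group: str = ""
    source: str = ""  # occupancy | SSF-All | SSF-Travel
    curve: str = ""
    member: str = ""  # species or individual for per-layer surfaces

    @property
    def data(self) -> np.ndarray:
        return self.raster.data

    def tag(self) -> str:
        parts = [p for p in (self.group, self.source, self.curve, self.member) if p]
        return "_".join(parts)


def transform(hs, curve: TransformationCurve):
    """Apply a suitability-to-resistance curve elementwise.

    ``hs`` may be a scalar, array, or :class:`Raster`; values must lie in
    [0, 1] (out of range raises — surfacing standardization bugs beats
    silently clamping them).  Nodata (NaN) propagates.
    """
    is_raster = isinstance(hs, Raster)
    vals = hs.data if is_raster else np.asarray(hs, dtype=float)
    flat = np.atleast_1d(vals)
    finite = flat[~np.isnan(flat)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("habitat suitability must lie in [0, 1]")
    if curve.kind == "linear":
        out = 100.0 - 100.0 * vals
    else:
        c = float(curve.c)
        out = 100.0 - 99.0 * (1.0 - np.exp(-c * vals)) / (1.0 - np.exp(-c))
    if is_raster:
        return hs.like(np.asarray(out))
    return out


def combine_group(surfaces: list[ResistanceSurface], group: str,
                  source: str = "", curve: str = "") -> ResistanceSurface:
    """Standardize-average-rescale member surfaces into one group surface.

    Each member surface is z-scored over its valid cells (making occupancy-
    and SSF-derived members commensurable), averaged cellwise, then min-max
    rescaled to span exactly [1, 1000].
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two member surfaces")
    base = surfaces[0].raster
    acc = np.zeros(base.shape)
    for s in surfaces:
        base.require_same_grid(s.raster)
        vals = s.raster.data
        m = vals[~np.isnan(vals)]
        if m.size == 0 or m.std() == 0:
            raise ValueError(f"constant member surface {s.tag() or '<unnamed>'}")
        acc = acc + (vals - m.mean()) / m.std()
    mean = acc / len(surfaces)
    valid = ~np.isnan(mean)
    lo, hi = mean[valid].min(), mean[valid].max()
    if hi == lo:
        raise ValueError("combined surface is constant; cannot rescale")
    scaled = 1.0 + 999.0 * (mean - lo) / (hi - lo)
    return ResistanceSurface(base.like(scaled), group=group, source=source,
                             curve=curve)


def burn_barriers(surface: ResistanceSurface, barrier_mask: Raster,
                  fraction: float) -> ResistanceSurface:
    """Set barrier cells to fraction x the pre-burn surface maximum.

    An empty mask is the identity.  The maximum is taken before burning, so
    repeated application is idempotent for fraction <= 1.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    surface.raster.require_same_grid(barrier_mask)
    mask = np.nan_to_num(barrier_mask.data, nan=0.0) > 0.5
    vals = surface.raster.data.copy()
    if mask.any():
        vmax = np.nanmax(vals)
        vals[mask & ~np.isnan(vals)] = fraction * vmax
    return ResistanceSurface(surface.raster.like(vals), surface.group,
                             surface.source, surface.curve, surface.member)
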