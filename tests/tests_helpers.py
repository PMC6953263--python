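"""Shared independent oracles and simulators for the test suite."""

import itertools

import numpy as np
import pandas as pd

from connectscape.raster import Raster
from connectscape.ssf import StepSet


def enumerate_min_cost(grid: Raster, start, goal):
    """Brute-force least cost over all simple 8-connected paths (DFS with
    branch-and-bound); independent of the Dijkstra implementation."""
    vals = grid.data
    nrow, ncol = vals.shape
    best = [np.inf]

    def neighbors(r, c):
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and not np.isnan(vals[rr, cc]):
                mult = np.sqrt(2) if dr and dc else 1.0
                yield rr, cc, 0.5 * (vals[r, c] + vals[rr, cc]) * grid.cell_size * mult

    def dfs(r, c, cost, seen):
        if cost >= best[0]:
            return
        if (r, c) == goal:
            best[0] = cost
            return
        for rr, cc, w in neighbors(r, c):
            if (rr, cc) not in seen:
                dfs(rr, cc, cost + w, seen | {(rr, cc)})

    dfs(*start, 0.0, {start})
    return best[0]


def simulate_strata(beta, n_strata, K, seed, p=None):
    """Direct conditional-logit data: softmax choice among K+1 candidates
    with iid standard-normal covariates."""
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(beta)
    p = p or len(beta)
    X = rng.standard_normal((n_strata, K + 1, p))
    w = np.exp(X @ beta)
    chosen = np.array([rng.choice(K + 1, p=wi / wi.sum()) for wi in w])
    names = [f"v{k}" for k in range(p)]
    frames = []
    for s in range(n_strata):
        df = pd.DataFrame(X[s], columns=names)
        df.insert(0, "case", (np.arange(K + 1) == chosen[s]).astype(int))
        df.insert(0, "stratum", s)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["x_start"] = out["y_start"] = out["x_end"] = out["y_end"] = 0.0
    out["length"] = 1.0
    return StepSet(out, names, K=K)
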