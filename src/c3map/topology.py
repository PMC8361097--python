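"""Hexagonal-grid ring neighborhoods and concurrence testing.

Spot arrays use Visium-style array coordinates: integer (x, y) with x + y
parity constant across the grid, so the six immediate neighbors of a spot
are (x±1, y±1) and (x±2, y).  Ring k around a reference spot is read off
the coordinate formula (x-(k+1), y±(k+1)); (x, y±(k+2)); (x+(k+1),
y±(k+1)): six axial positions per k.  For odd k the (x, y±(k+2)) offsets
leave the parity lattice and are reported as missing; a full-ring mode
returning the complete hexagonal ring is available as an alternative.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .signatures import _dense


def hex_ring(
    center: tuple[int, int],
    k: int,
    grid: set[tuple[int, int]] | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """The six ring-k coordinates around ``center``; k=0 is the 6 neighbors.

    Returns (present, missing): positions found on ``grid`` and positions
    absent from it (off the grid edge or off the parity lattice).  With no
    grid, all six formula positions are returned as present.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    x, y = center
    coords = [
        (x - (k + 1), y + (k + 1)),
        (x - (k + 1), y - (k + 1)),
        (x, y + (k + 2)),
        (x, y - (k + 2)),
        (x + (k + 1), y + (k + 1)),
        (x + (k + 1), y - (k + 1)),
    ]
    if grid is None:
        return coords, []
    present = [c for c in coords if c in grid]
    missing = [c for c in coords if c not in grid]
    return present, missing


def full_hex_ring(
    center: tuple[int, int],
    k: int,
    grid: set[tuple[int, int]] | None = None,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Complete hexagonal ring at distance k+1 (6*(k+1) positions).

    Works in axial coordinates q = (y - x) / 2, r = x (the orientation in
    which the six immediate neighbors are (x±1, y±1) and (x, y±2), as in
    the printed ring formula at k = 0), walking the ring of radius k+1 and
    mapping back to array coordinates, so every position respects the
    parity rule by construction.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    x, y = center
    q0, r0 = (y - x) // 2, x
    radius = k + 1
    directions = [(0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0)]
    q, r = q0 + radius, r0 - radius  # start at the (1, -1) corner
    coords = []
    for dq, dr in directions:
        for _ in range(radius):
            coords.append((r, 2 * q + r))
            q, r = q + dq, r + dr
    if grid is None:
        return coords, []
    return [c for c in coords if c in grid], [c for c in coords if c not in grid]


def reference_spots(
    scores: pd.Series | np.ndarray, top_pct: float = 5.0
) -> np.ndarray:
    """Boolean mask of reference spots: score >= the (100 - top_pct)th pctile.

    Ties at the cutoff are included.  Constant scores select every spot,
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no spots")
    if np.all(scores == scores[0]):
        warnings.warn("constant module scores: every spot is a reference")
        return np.ones(scores.shape, dtype=bool)
    cutoff = np.percentile(scores, 100 - top_pct)
    return scores >= cutoff


def ring_profile(
    spots: ad.AnnData,
    references: np.ndarray,
    gene: str,
    max_k: int = 3,
    use_full_ring: bool = False,
) -> pd.Series:
    """Mean expression of ``gene`` by ring index around the reference spots.

    For each reference, ring k's mean is taken over the ring positions
    that exist on the grid (missing positions are excluded, never
    zero-filled); k = -1 denotes the reference spot itself.  Profiles are
    averaged over references; a ring with no existing spot anywhere stays
    missing (NaN).  Expression should be log-normalized.
    """
    ring_fn = full_hex_ring if use_full_ring else hex_ring
    coords = list(zip(spots.obs["array_x"].astype(int), spots.obs["array_y"].astype(int)))
    index_of = {c: i for i, c in enumerate(coords)}
    grid = set(index_of)
    expr = _dense(spots[:, [gene]].X).ravel()

    ref_idx = np.where(np.asarray(references, dtype=bool))[0]
    if ref_idx.size == 0:
        raise ValueError("no reference spots")
    profiles = np.full((len(ref_idx), max_k + 2), np.nan)
    for i, ri in enumerate(ref_idx):
        profiles[i, 0] = expr[ri]
        for k in range(max_k + 1):
            present, _ = ring_fn(coords[ri], k, grid)
            if present:
                profiles[i, k + 1] = expr[[index_of[c] for c in present]].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN ring
        mean_profile = np.nanmean(profiles, axis=0)
    return pd.Series(mean_profile, index=[-1] + list(range(max_k + 1)), name=gene)


def standardize_profiles(profiles: dict[str, pd.Series]) -> pd.DataFrame:
    """z-score ring profiles across modules (for a common gene).

    Takes module name -> ring profile and standardizes each ring index
    across the modules, as done for display of the field profiles.
    """
    df = pd.DataFrame(profiles)
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    return df.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)


def concurrence_test(
    module_scores: pd.Series | np.ndarray,
    gene_expression: pd.Series | np.ndarray,
    top_pct: float = 5.0,
) -> tuple[float, float, np.ndarray]:
    """Fisher test of gene-expression enrichment in module-high spots.

    Spots in the top and bottom ``top_pct`` percent of the module score
    form the two strata; gene expression is dichotomized at its own top
    ``top_pct`` percentile over all spots.  Returns (odds ratio, one-sided
    p for enrichment in the top stratum, 2x2 table).
    """
    scores = np.asarray(module_scores, dtype=float)
    expr = np.asarray(gene_expression, dtype=float)
    if scores.shape != expr.shape:
        raise ValueError("scores and expression must align")
    hi_cut = np.percentile(scores, 100 - top_pct)
    lo_cut = np.percentile(scores, top_pct)
    top = scores >= hi_cut
    bottom = scores <= lo_cut
    expr_hi = expr >= np.percentile(expr, 100 - top_pct)

    table = np.array(
        [
            [int((top & expr_hi).sum()), int((top & ~expr_hi).sum())],
            [int((bottom & expr_hi).sum()), int((bottom & ~expr_hi).sum())],
        ]
    )
    odds, p = fisher_exact(table, alternative="greater")
    return float(odds), float(p), table
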