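"""PSU-level category proportions, tri-colour map data, and Moran's I.

The map stage summarises each primary sampling unit by the share of its
respondents assigned to the three dominant empowerment categories and
encodes those shares as an additively blended colour — blue for "more
empowered" (category 1), red for "less empowered" (category 2) and green
for the "modal empowered" reference (category 3).  Categories 4 and 5 are
excluded from both numerator and denominator.

Moran's I measures global spatial autocorrelation of a vector of values
under a nonnegative spatial weight matrix (row-standardised here); its
permutation-null expectation is -1/(n-1).  Two weighting modes are
offered for the model's PSU effects, since the aggregation is a genuine
analysis choice: region-median aggregation with first-order region
adjacency (the primary mode), or direct PSU-level k-nearest-neighbour
binary weights.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .clustering import ClusterAssignment
from .synthetic import RegionGraph

MAP_COLUMNS = [
    "psu", "region", "lon", "lat", "n1", "n2", "n3",
    "p1", "p2", "p3", "hex_color",
]


def blend_rgb(p1: float, p2: float, p3: float) -> tuple[int, int, int]:
    """Blend category proportions into an (r, g, b) triple in 0..255.

    The red channel carries the "less empowered" share p2, green the
    "modal" share p3 and blue the "more empowered" share p1.
    """
    total = p1 + p2 + p3
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {total!r})")
    if min(p1, p2, p3) < 0:
        raise ValueError("proportions must be nonnegative")
    return (round(255 * p2), round(255 * p3), round(255 * p1))


def _hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def psu_proportions(
    assignment: ClusterAssignment | np.ndarray, data: pd.DataFrame
) -> pd.DataFrame:
    """Per-PSU counts and proportions over categories 1-3 (MAP_COLUMNS schema).

    PSUs whose respondents all fall in categories 4-5 get zero counts, NaN
    proportions and an empty colour, and are flagged via ``has_dominant``.
    """
    labels = (
        assignment.labels
        if isinstance(assignment, ClusterAssignment)
        else np.asarray(assignment)
    )
    if len(labels) != len(data):
        raise ValueError("labels and survey table disagree in length")
    df = data[["psu", "region", "lon", "lat"]].copy()
    df["category"] = labels
    rows = []
    for psu, grp in df.groupby("psu", sort=True):
        counts = [int((grp["category"] == k).sum()) for k in (1, 2, 3)]
        denom = sum(counts)
        if denom > 0:
            props = [c / denom for c in counts]
            color = _hex(blend_rgb(*props))
        else:
            props = [np.nan] * 3
            color = ""
        rows.append(
            {
                "psu": psu,
                "region": grp["region"].iloc[0],
                "lon": grp["lon"].iloc[0],
                "lat": grp["lat"].iloc[0],
                "n1": counts[0], "n2": counts[1], "n3": counts[2],
                "p1": props[0], "p2": props[1], "p3": props[2],
                "hex_color": color,
                "has_dominant": denom > 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Moran's I


def morans_i(values, weights) -> float:
    """Global Moran's I with row-standardised weights.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 units")
    if w.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if np.diagonal(w).any():
        raise ValueError("weight matrix must have a zero diagonal")
    row_sums = w.sum(axis=1)
    keep = row_sums > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} unit(s) with empty weight rows",
            stacklevel=2,
        )
        x = x[keep]
        w = w[np.ix_(keep, keep)]
        row_sums = w.sum(axis=1)
        if (row_sums == 0).any():
            raise ValueError("weight matrix still has empty rows after dropping")
        n = x.size
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = w / row_sums[:, None]
    z = x - x.mean()
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def region_adjacency_weights(graph: RegionGraph) -> np.ndarray:
    """Binary first-order adjacency weights in region_ids order."""
    return graph.adjacency_matrix()


def knn_weights(points: np.ndarray, k: int = 10) -> np.ndarray:
    """Symmetrised binary k-nearest-neighbour weights for PSU point locations."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n <= k:
        raise ValueError("need more points than neighbours")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        w[i, idx[i, 1:]] = 1.0
    return np.maximum(w, w.T)


def psu_effect_morans(
    psu_medians: np.ndarray,
    psu_regions: np.ndarray,
    graph: RegionGraph,
    mode: str = "region_median",
    psu_points: np.ndarray | None = None,
    k: int = 10,
) -> float:
    """Moran's I of posterior-median PSU effects under a named weighting mode.

    ``region_median`` (primary): aggregate the PSU-specific posterior
    medians to their region median and use first-order region adjacency.
    ``knn``: compute I directly on PSU points with symmetrised binary
    k-nearest-neighbour weights.
    """
    med = np.asarray(psu_medians, dtype=float)
    if mode == "region_median":
        regions = np.asarray(psu_regions)
        agg = np.array(
            [np.median(med[regions == r]) for r in graph.region_ids]
        )
        return morans_i(agg, region_adjacency_weights(graph))
    if mode == "knn":
        if psu_points is None:
            raise ValueError("knn mode requires PSU point coordinates")
        return morans_i(med, knn_weights(psu_points, k=k))
    raise ValueError(f"unknown mode {mode!r}")
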