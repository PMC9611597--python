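"""Design construction for the multinomial logit geo-additive model.

The fixed-effect design X is n x 8: an intercept plus dummy codes for
urban residence (reference rural), education primary / secondary+
(reference none) and income quintiles poorer / middle / richer / richest
(reference poorest).  The age smooth uses a cubic B-spline basis on 20
equidistant interior intervals, giving M = 20 + 3 = 23 basis functions
whose rows sum to one on the knot span.  Respondents outside the three
dominant categories are dropped before any matrix is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .clustering import ClusterAssignment
from .synthetic import EDUC_LEVELS, INCOME_LEVELS


@dataclass
class DesignMatrices:
    """Model matrices plus the nesting maps for PSU and region effects."""

    X: np.ndarray  # (n, 8)
    B: np.ndarray  # (n, M) age spline basis
    Y: np.ndarray  # (n, 3) one-hot category indicators
    psu_index: np.ndarray  # respondent -> PSU position (0-based)
    region_index: np.ndarray  # respondent -> region position (0-based)
    psu_ids: np.ndarray
    region_ids: np.ndarray
    ages: np.ndarray
    knots: np.ndarray  # full (extended) knot vector of the basis

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_psu(self) -> int:
        return len(self.psu_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def bspline_basis(
    ages, n_intervals: int = 20, degree: int = 3, span: tuple | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis on equidistant knots; returns (basis, knot_vector).

    The span [min age, max age] (or an explicit ``span``) is divided into
    ``n_intervals`` equal intervals; boundary knots are extended outwards
    with the same spacing.  The number of basis functions is
    ``n_intervals + degree`` (23 with the defaults).  Ages outside the span
    are clamped to the boundary with a warning.
    """
    if n_intervals < degree + 1:
        raise ValueError("need at least degree+1 knot intervals")
    a = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = (a.min(), a.max()) if span is None else span
    if hi <= lo:
        raise ValueError("degenerate age span")
    if (a < lo).any() or (a > hi).any():
        warnings.warn("ages outside the knot span clamped to the boundary",
                      stacklevel=2)
        a = np.clip(a, lo, hi)
    breaks = np.linspace(lo, hi, n_intervals + 1)
    h = breaks[1] - breaks[0]
    knots = np.concatenate([
        lo + h * np.arange(-degree, 0), breaks, hi + h * np.arange(1, degree + 1)
    ])
    m = len(knots) - degree - 1  # = n_intervals + degree
    basis = np.empty((a.size, m))
    # evaluate just inside the right boundary so the last basis value is 1-sided
    a_eval = np.minimum(a, hi - 1e-9 * h)
    design = BSpline.design_matrix(a_eval, knots, degree).toarray()
    basis[:, :] = design
    return basis, knots


def rw2_penalty(m: int) -> np.ndarray:
    """Second-order random-walk penalty K = D2' D2 (rank m-2).

    Its null space is spanned by constant and linear trends in the
    coefficient index, matching the improper flat initialisation of the
    random walk.
    """
    d2 = np.diff(np.eye(m), n=2, axis=0)
    return d2.T @ d2


def build_design(
    data: pd.DataFrame,
    labels,
    n_intervals: int = 20,
    degree: int = 3,
) -> DesignMatrices:
    """Assemble model matrices from the survey table and category labels.

    Respondents labelled 4 or 5 are excluded; labels must be in 1..5.
    """
    lab = (
        labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    )
    if len(lab) != len(data):
        raise ValueError("labels and survey table disagree in length")
    if lab.min() < 1 or lab.max() > 5:
        raise ValueError("labels must lie in 1..5")
    keep = lab <= 3
    df = data.loc[keep].reset_index(drop=True)
    lab = lab[keep]
    n = len(df)
    if n == 0:
        raise ValueError("no respondents in the three dominant categories")

    for col, levels in (("educ", EDUC_LEVELS), ("income", INCOME_LEVELS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            i = df.index[bad][0]
            raise ValueError(
                f"respondent {df.loc[i, 'resp_id']}: unknown {col} level "
                f"{df.loc[i, col]!r}"
            )

    x = np.ones((n, 8))
    x[:, 1] = df["urban"].to_numpy(dtype=float)
    x[:, 2] = (df["educ"] == "primary").to_numpy(dtype=float)
    x[:, 3] = (df["educ"] == "secondary+").to_numpy(dtype=float)
    for q, level in enumerate(INCOME_LEVELS[1:], start=4):
        x[:, q] = (df["income"] == level).to_numpy(dtype=float)

    ages = df["age"].to_numpy(dtype=float)
    basis, knots = bspline_basis(ages, n_intervals=n_intervals, degree=degree)

    y = np.zeros((n, 3), dtype=np.int8)
    y[np.arange(n), lab - 1] = 1

    psu_ids, psu_index = np.unique(df["psu"].to_numpy(), return_inverse=True)
    region_ids, region_index = np.unique(df["region"].to_numpy(), return_inverse=True)
    return DesignMatrices(
        X=x, B=basis, Y=y,
        psu_index=psu_index, region_index=region_index,
        psu_ids=psu_ids, region_ids=region_ids,
        ages=ages, knots=knots,
    )
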