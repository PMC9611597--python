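"""Synthetic DHS-like survey generator with a known geo-additive ground truth.

Real individual-recode DHS microdata are access-restricted, so every stage
of the pipeline is exercised against data simulated from the same model
family the estimator assumes: respondents nested in primary sampling units
(PSUs) nested in first-level administrative regions, with

    eta_ijk = x_ij beta_k + f_k(age_ij) + b_{u(ij),k} + s_{jk},  k = 1, 2

driving a 3-category multinomial label (category 3 is the reference,
eta_ij3 = 0), which is then rendered into the ten categorical items by
corrupting a category-specific response template with independent
flip-noise of rate epsilon per item.

Regions are a synthetic rook-adjacency lattice standing in for real
administrative geography; region effects s_k come from an intrinsic
Gaussian Markov random field on that lattice.  PSU coordinates mimic the
DHS anonymisation scheme: the published point is displaced from the true
location by up to 2 km in urban PSUs and up to 5 km in rural ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.sparse import csgraph, csr_matrix

from .items import ITEMS, N_LEVELS, ResponseVector, encode_responses

KM_PER_DEGREE = 111.32  # mean meridian arc length; adequate for jitter caps
URBAN_JITTER_KM = 2.0
RURAL_JITTER_KM = 5.0

SURVEY_COLUMNS = [
    "resp_id", "region", "psu", "lon", "lat", "age", "urban", "educ", "income",
    *ITEMS,
]

EDUC_LEVELS = ("none", "primary", "secondary+")
INCOME_LEVELS = ("poorest", "poorer", "middle", "richer", "richest")


# ---------------------------------------------------------------------------
# Region adjacency


@dataclass(frozen=True)
class RegionGraph:
    """Adjacency structure of the J first-level regions.

    Two regions are neighbours when they share a boundary; adjacency is
    symmetric with no self-loops.  Regions without any neighbour are
    tracked as islands and excluded from the intrinsic MRF prior.
    """

    region_ids: tuple
    neighbors: dict

    def __post_init__(self):
        for j, nbrs in self.neighbors.items():
            if j in nbrs:
                raise ValueError(f"self-loop at region {j!r}")
            for j2 in nbrs:
                if j not in self.neighbors.get(j2, ()):
                    raise ValueError(f"asymmetric adjacency {j!r} -> {j2!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def islands(self) -> tuple:
        return tuple(j for j in self.region_ids if not self.neighbors[j])

    def degree(self, region) -> int:
        return len(self.neighbors[region])

    def index_of(self, region) -> int:
        return self.region_ids.index(region)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency in region_ids order."""
        idx = {r: i for i, r in enumerate(self.region_ids)}
        a = np.zeros((self.n_regions, self.n_regions))
        for j, nbrs in self.neighbors.items():
            for j2 in nbrs:
                a[idx[j], idx[j2]] = 1.0
        return a

    def structure_matrix(self) -> np.ndarray:
        """Graph Laplacian Q = diag(N_j) - A, the intrinsic GMRF structure."""
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def connected_components(self) -> list[list]:
        a = csr_matrix(self.adjacency_matrix())
        n_comp, labels = csgraph.connected_components(a, directed=False)
        return [
            [r for r, lab in zip(self.region_ids, labels) if lab == c]
            for c in range(n_comp)
        ]


def build_region_lattice(rows: int, cols: int) -> RegionGraph:
    """Rook-adjacency grid of ``rows x cols`` regions, ids 1..rows*cols row-major."""
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if rows * cols < 2:
        raise ValueError("lattice needs at least 2 regions")
    ids = tuple(range(1, rows * cols + 1))
    neighbors: dict[int, set] = {i: set() for i in ids}
    for r in range(rows):
        for c in range(cols):
            me = r * cols + c + 1
            if c + 1 < cols:
                neighbors[me].add(me + 1)
                neighbors[me + 1].add(me)
            if r + 1 < rows:
                neighbors[me].add(me + cols)
                neighbors[me + cols].add(me)
    return RegionGraph(ids, {k: frozenset(v) for k, v in neighbors.items()})


def lattice_centroids(rows: int, cols: int, cell_deg: float = 0.5) -> np.ndarray:
    """(J, 2) lon/lat centroids of the lattice cells, row-major order."""
    lon = (np.arange(cols) + 0.5) * cell_deg
    lat = (np.arange(rows) + 0.5) * cell_deg
    gx, gy = np.meshgrid(lon, lat)
    return np.column_stack([gx.ravel(), gy.ravel()])


def sample_intrinsic_gmrf(
    graph: RegionGraph, tau2: float, seed=None
) -> np.ndarray:
    """One draw of region effects from the intrinsic GMRF, centred to sum zero.

    The improper joint density is prop. to exp(-s' Q s / (2 tau2)) with Q the
    graph Laplacian; conditionally each s_j is Normal with mean the average
    of its neighbours and variance tau2 / N_j.  Sampling is done in the
    eigenbasis of Q restricted to its positive eigenvalues (the orthogonal
    complement of the constant null space), which imposes sum(s) = 0.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    comps = graph.connected_components()
    if len(comps) > 1:
        raise ValueError(
            f"region graph is disconnected ({len(comps)} components): {comps}"
        )
    rng = np.random.default_rng(seed)
    q = graph.structure_matrix()
    w, v = sla.eigh(q)
    pos = w > 1e-10 * w.max()
    z = rng.standard_normal(pos.sum())
    s = v[:, pos] @ (z * np.sqrt(tau2 / w[pos]))
    return s - s.mean()


# ---------------------------------------------------------------------------
# Response templates and item-level noise


def final_modes() -> list[ResponseVector]:
    """The five converged response templates, one per empowerment category.

    1 "more empowered":  violence no, decisions with partner, refuse-sex yes
    2 "less empowered":  violence yes, decisions partner alone, refuse-sex no
    3 "modal empowered": violence no, decisions partner alone, refuse-sex yes
    4 "autonomous":      violence no, visit/purchase/health self but spending
                         decided by the partner, refuse-sex yes
    5 "other":           violence don't know, decisions partner, refuse-sex no
    """
    v = ResponseVector
    return [
        v("no", "no", "no", "no", "no",
          "with_partner", "with_partner", "with_partner", "with_partner", "yes"),
        v("yes", "yes", "yes", "yes", "yes",
          "partner", "partner", "partner", "partner", "no"),
        v("no", "no", "no", "no", "no",
          "partner", "partner", "partner", "partner", "yes"),
        v("no", "no", "no", "no", "no",
          "self", "self", "self", "partner", "yes"),
        v("dont_know", "dont_know", "dont_know", "dont_know", "dont_know",
          "partner", "partner", "partner", "partner", "no"),
    ]


def emit_responses(
    category: int,
    templates: list[ResponseVector],
    epsilon: float,
    seed=None,
    size: int = 1,
) -> np.ndarray:
    """Draw ``size`` noisy copies of the category's template, as a code matrix.

    Independently with probability ``epsilon`` each of the 10 items is
    replaced by a uniformly chosen *different* admissible level.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if not 1 <= category <= len(templates):
        raise ValueError(f"category {category} outside 1..{len(templates)}")
    rng = np.random.default_rng(seed)
    base = templates[category - 1].to_codes()
    codes = np.tile(base, (size, 1))
    flip = rng.random((size, 10)) < epsilon
    # uniform over the other L-1 levels: shift by 1..L-1 modulo L
    shift = rng.integers(1, N_LEVELS[None, :], size=(size, 10), endpoint=False)
    codes[flip] = (codes[flip] + shift[flip]) % np.broadcast_to(
        N_LEVELS, (size, 10)
    )[flip]
    return codes.astype(np.int8)


# ---------------------------------------------------------------------------
# Ground truth and covariates


@dataclass
class GroundTruth:
    """Generating values of the geo-additive predictor, kept for recovery tests.

    beta has shape (2, 8) — rows are the two non-reference categories, columns
    the intercept plus the seven covariate dummies.  ``age_fn`` maps an age
    array to the (2, n) smooth age contribution.  ``s`` (2, J) and ``b``
    (2, n_psu) are filled in by :func:`simulate_survey` when absent.
    """

    beta: np.ndarray
    psu_sd: float = 0.3
    region_sd: float = 0.6
    epsilon: float = 0.05
    age_fn: object = None
    s: np.ndarray | None = None
    b: np.ndarray | None = None
    labels: np.ndarray | None = None  # generating category per respondent
    psu_region: np.ndarray | None = None  # region index per PSU (0-based)
    psu_urban: np.ndarray | None = None
    psu_true_xy: np.ndarray | None = None  # pre-jitter PSU locations (lon, lat)
    psu_xy: np.ndarray | None = None  # published (jittered) locations

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (2, 8):
            raise ValueError("beta must have shape (2, 8)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.age_fn is None:
            self.age_fn = default_age_fn

    def age_effect(self, ages: np.ndarray) -> np.ndarray:
        out = np.asarray(self.age_fn(np.asarray(ages, dtype=float)))
        if out.shape != (2, len(np.atleast_1d(ages))):
            raise ValueError("age_fn must return shape (2, n)")
        return out


def default_age_fn(ages: np.ndarray) -> np.ndarray:
    """Smooth, centred age effects: gentle hump for k=1, decline for k=2."""
    a = (np.asarray(ages, dtype=float) - 32.0) / 17.0  # roughly [-1, 1]
    f1 = 0.6 * np.sin(np.pi * a / 1.6)
    f2 = -0.5 * a + 0.25 * a**2
    return np.vstack([f1 - f1.mean(), f2 - f2.mean()])


def zero_age_fn(ages: np.ndarray) -> np.ndarray:
    a = np.atleast_1d(np.asarray(ages, dtype=float))
    return np.zeros((2, a.size))


@dataclass
class CovariateConfig:
    """Marginal covariate distributions, optionally varying by region.

    ``educ_probs`` / ``income_probs`` may be a single probability vector or a
    (J, L) array giving per-region compositions — the latter deliberately
    confounds composition with space, to test that the model separates the
    structured region effect from covariate composition.
    """

    age_range: tuple[int, int] = (15, 49)
    urban_prob: float = 0.4
    educ_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.45, 0.30, 0.25])
    )
    income_probs: np.ndarray = field(default_factory=lambda: np.full(5, 0.2))

    def _probs_for(self, probs, n_levels, region_index, n_regions):
        p = np.asarray(probs, dtype=float)
        if p.ndim == 1:
            if p.size != n_levels:
                raise ValueError("probability vector has wrong length")
            return np.tile(p / p.sum(), (n_regions, 1))[region_index]
        if p.shape != (n_regions, n_levels):
            raise ValueError("per-region probabilities must be (J, L)")
        return (p / p.sum(axis=1, keepdims=True))[region_index]


def _draw_categorical(rng, probs_rows: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw given an (n, L) matrix of probabilities."""
    u = rng.random(probs_rows.shape[0])
    return (probs_rows.cumsum(axis=1) < u[:, None]).sum(axis=1)


# ---------------------------------------------------------------------------
# Survey simulation


def simulate_survey(
    graph: RegionGraph,
    ground_truth: GroundTruth,
    psus_per_region: int = 5,
    respondents_per_psu_range: tuple[int, int] = (15, 100),
    covariate_config: CovariateConfig | None = None,
    seed=None,
    lattice_shape: tuple[int, int] | None = None,
    n_categories: int = 3,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a nested survey from the geo-additive ground truth.

    Returns the respondent table (one row each, SURVEY_COLUMNS schema) and
    the completed ground truth (region effects, PSU effects and generating
    labels filled in).  With ``n_categories=5`` a small share of respondents
    is additionally drawn from the autonomous/other templates to exercise
    the full k = 5 clustering stage; the model stage uses categories 1-3.
    """
    if psus_per_region < 1:
        raise ValueError("need at least one PSU per region")
    lo, hi = respondents_per_psu_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid respondents-per-PSU range")
    if n_categories not in (3, 5):
        raise ValueError("n_categories must be 3 or 5")
    cfg = covariate_config or CovariateConfig()
    gt = ground_truth
    rng = np.random.default_rng(seed)
    J = graph.n_regions

    if lattice_shape is None:
        # squarest factorisation of J for centroid placement
        r = int(np.sqrt(J))
        while J % r:
            r -= 1
        lattice_shape = (r, J // r)
    if lattice_shape[0] * lattice_shape[1] != J:
        raise ValueError("lattice_shape inconsistent with graph size")
    centroids = lattice_centroids(*lattice_shape)
    cell = 0.5

    if gt.s is None:
        gt.s = np.vstack([
            sample_intrinsic_gmrf(graph, gt.region_sd**2, rng)
            for _ in range(2)
        ])
    s = np.asarray(gt.s, dtype=float)
    if s.shape != (2, J):
        raise ValueError("ground-truth region effects must be (2, J)")

    n_psu = J * psus_per_region
    psu_region_index = np.repeat(np.arange(J), psus_per_region)
    psu_urban = rng.random(n_psu) < cfg.urban_prob
    if gt.b is None:
        gt.b = rng.normal(0.0, gt.psu_sd, size=(2, n_psu))
    b = np.asarray(gt.b, dtype=float)
    if b.shape != (2, n_psu):
        raise ValueError("ground-truth PSU effects must be (2, n_psu)")

    # PSU locations: uniform within the region cell, then DHS-style jitter
    true_xy = centroids[psu_region_index] + rng.uniform(
        -cell / 2 * 0.9, cell / 2 * 0.9, size=(n_psu, 2)
    )
    cap_km = np.where(psu_urban, URBAN_JITTER_KM, RURAL_JITTER_KM)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_psu)
    dist_deg = rng.uniform(0.0, cap_km) / KM_PER_DEGREE
    psu_xy = true_xy + dist_deg[:, None] * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )

    counts = rng.integers(lo, hi + 1, size=n_psu)
    psu_index = np.repeat(np.arange(n_psu), counts)
    n = int(counts.sum())
    region_index = psu_region_index[psu_index]

    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    urban = psu_urban[psu_index]
    educ = _draw_categorical(
        rng, cfg._probs_for(cfg.educ_probs, 3, region_index, J)
    )
    income = _draw_categorical(
        rng, cfg._probs_for(cfg.income_probs, 5, region_index, J)
    )

    x = np.ones((n, 8))
    x[:, 1] = urban
    x[:, 2] = educ == 1
    x[:, 3] = educ == 2
    for q in range(1, 5):
        x[:, 3 + q] = income == q

    eta = (
        gt.beta @ x.T
        + gt.age_effect(ages)
        + b[:, psu_index]
        + s[:, region_index]
    )  # (2, n)
    # multinomial probabilities with eta_3 = 0 as reference
    m = np.maximum(np.max(eta, axis=0), 0.0)
    e1 = np.exp(eta[0] - m)
    e2 = np.exp(eta[1] - m)
    e3 = np.exp(-m)
    denom = e1 + e2 + e3
    probs = np.column_stack([e1, e2, e3]) / denom[:, None]
    labels = 1 + _draw_categorical(rng, probs)

    if n_categories == 5:
        # overwrite a small share with the minority templates
        minority = rng.random(n) < 0.08
        labels[minority] = rng.choice([4, 5], p=[0.9, 0.1], size=minority.sum())

    templates = final_modes()
    codes = np.empty((n, 10), dtype=np.int8)
    for cat in np.unique(labels):
        mask = labels == cat
        codes[mask] = emit_responses(
            int(cat), templates, gt.epsilon,
            seed=rng.integers(2**31), size=int(mask.sum()),
        )

    from .items import ITEM_LEVELS  # local to avoid cycle at import time

    data = {
        "resp_id": np.arange(1, n + 1),
        "region": np.asarray(graph.region_ids)[region_index],
        "psu": psu_index + 1,
        "lon": psu_xy[psu_index, 0],
        "lat": psu_xy[psu_index, 1],
        "age": ages,
        "urban": urban.astype(int),
        "educ": np.asarray(EDUC_LEVELS)[educ],
        "income": np.asarray(INCOME_LEVELS)[income],
    }
    for i, item in enumerate(ITEMS):
        data[item] = np.asarray(ITEM_LEVELS[item])[codes[:, i]]
    df = pd.DataFrame(data, columns=SURVEY_COLUMNS)
    gt.labels = labels
    gt.psu_region = psu_region_index
    gt.psu_urban = psu_urban
    gt.psu_true_xy = true_xy
    gt.psu_xy = psu_xy
    return df, gt
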