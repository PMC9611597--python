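"""Plain-text I/O: respondent tables, region adjacency files, ground truth.

Formats:

* Survey table — CSV with the fixed header ``resp_id, region, psu, lon,
  lat, age, urban, educ, income`` followed by the ten item columns.
* Region graph — BayesX-style layout: first line the number of regions J;
  then, per region, three lines holding the region id, its neighbour
  count N_j, and the N_j neighbour ids.
* Ground truth — a JSON sidecar used only by test harnesses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .items import ITEM_LEVELS, ITEMS
from .synthetic import (
    EDUC_LEVELS,
    INCOME_LEVELS,
    SURVEY_COLUMNS,
    GroundTruth,
    RegionGraph,
)


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    """Check the schema and the complete-case contract; return the frame."""
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    if df[SURVEY_COLUMNS].isna().any().any():
        raise ValueError("survey table contains missing values (complete cases only)")
    for item in ITEMS:
        bad = ~df[item].isin(ITEM_LEVELS[item])
        if bad.any():
            i = df.index[bad][0]
            raise ValueError(
                f"respondent {df.loc[i, 'resp_id']}: inadmissible level "
                f"{df.loc[i, item]!r} for item {item!r}"
            )
    if not df["educ"].isin(EDUC_LEVELS).all():
        raise ValueError("unknown education level in survey table")
    if not df["income"].isin(INCOME_LEVELS).all():
        raise ValueError("unknown income level in survey table")
    # each PSU must sit in exactly one region
    n_regions_per_psu = df.groupby("psu")["region"].nunique()
    if (n_regions_per_psu > 1).any():
        bad = n_regions_per_psu[n_regions_per_psu > 1].index.tolist()
        raise ValueError(f"PSUs spanning multiple regions: {bad}")
    return df


def write_survey(df: pd.DataFrame, path) -> None:
    validate_survey(df)
    df.to_csv(path, index=False, columns=SURVEY_COLUMNS)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={item: str for item in ITEMS})
    return validate_survey(df)


def write_graph(graph: RegionGraph, path) -> None:
    lines = [str(graph.n_regions)]
    for rid in graph.region_ids:
        nbrs = sorted(graph.neighbors[rid])
        lines.append(str(rid))
        lines.append(str(len(nbrs)))
        lines.append(" ".join(str(v) for v in nbrs))
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce_id(token: str):
    return int(token) if token.lstrip("-").isdigit() else token


def read_graph(path) -> RegionGraph:
    tokens = Path(path).read_text().split("\n")
    tokens = [t.strip() for t in tokens if t.strip()]
    j = int(tokens[0])
    pos = 1
    ids, neighbors = [], {}
    for _ in range(j):
        rid = _coerce_id(tokens[pos])
        n_nbr = int(tokens[pos + 1])
        nbrs = [] if n_nbr == 0 else tokens[pos + 2].split()
        if len(nbrs) != n_nbr:
            raise ValueError(f"region {rid}: expected {n_nbr} neighbours, got {len(nbrs)}")
        ids.append(rid)
        neighbors[rid] = frozenset(_coerce_id(t) for t in nbrs)
        pos += 3 if n_nbr > 0 else 2  # islands write an empty line, dropped on read
    return RegionGraph(tuple(ids), neighbors)


def write_ground_truth(gt: GroundTruth, path) -> None:
    def arr(x):
        return None if x is None else np.asarray(x).tolist()

    payload = {
        "beta": arr(gt.beta),
        "psu_sd": gt.psu_sd,
        "region_sd": gt.region_sd,
        "epsilon": gt.epsilon,
        "s": arr(gt.s),
        "b": arr(gt.b),
        "labels": arr(gt.labels),
        "age_grid": list(range(15, 50)),
        "age_effect": arr(gt.age_effect(np.arange(15, 50))) if gt.age_fn else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def arr(key):
        v = payload.get(key)
        return None if v is None else np.asarray(v)

    gt = GroundTruth(
        beta=np.asarray(payload["beta"]),
        psu_sd=payload["psu_sd"],
        region_sd=payload["region_sd"],
        epsilon=payload["epsilon"],
        s=arr("s"),
        b=arr("b"),
    )
    gt.labels = arr("labels")
    if payload.get("age_effect") is not None:
        grid = np.asarray(payload["age_grid"], dtype=float)
        vals = np.asarray(payload["age_effect"])

        def interp_age_fn(ages, _grid=grid, _vals=vals):
            a = np.atleast_1d(np.asarray(ages, dtype=float))
            return np.vstack([np.interp(a, _grid, _vals[k]) for k in range(2)])

        gt.age_fn = interp_age_fn
    return gt
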