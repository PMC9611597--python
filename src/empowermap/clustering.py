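"""k-modes classification of the ten categorical items into k = 5 categories.

k-modes is the k-means analogue for nominal data: the dissimilarity is the
simple matching distance (number of mismatching items) and each cluster
centre is a "mode" — the item-wise most frequent level among its members.
The algorithm is primed with five conceptually meaningful initial modes
(more empowered / less empowered / modal empowered / autonomous / other)
rather than random observations, so the converged categories keep their
interpretation.

This implementation iterates in batch (Lloyd-style): a full assignment
pass followed by a full mode-update pass, until no label changes.  All
tie-breaks are deterministic — nearest mode with the lowest index, and
plurality ties resolved to the lowest level in the declared level order —
so results are independent of respondent ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .items import ITEMS, N_LEVELS, ResponseVector, encode_responses


@dataclass
class ClusterAssignment:
    """Labels (1..k), converged modes, total matching cost and iteration count."""

    labels: np.ndarray
    modes: list[ResponseVector]
    cost: int
    n_iter: int
    converged: bool
    cost_history: list[int]

    @property
    def k(self) -> int:
        return len(self.modes)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def matching_distance(a: ResponseVector, b: ResponseVector) -> int:
    """Number of the ten items on which the two response vectors differ."""
    return int(np.sum(a.to_codes() != b.to_codes()))


def default_initial_modes() -> list[ResponseVector]:
    """The five priming modes, in category order 1..5.

    1 more empowered (violence no, decisions with partner, refuse-sex yes),
    2 less empowered (all opposite), 3 modal empowered (no / partner / yes),
    4 autonomous (decisions alone), 5 other (all neutral responses).
    """
    v = ResponseVector
    modes = [
        v("no", "no", "no", "no", "no",
          "with_partner", "with_partner", "with_partner", "with_partner", "yes"),
        v("yes", "yes", "yes", "yes", "yes",
          "partner", "partner", "partner", "partner", "no"),
        v("no", "no", "no", "no", "no",
          "partner", "partner", "partner", "partner", "yes"),
        v("no", "no", "no", "no", "no",
          "self", "self", "self", "self", "yes"),
        v("dont_know", "dont_know", "dont_know", "dont_know", "dont_know",
          "other", "other", "other", "other", "dont_know"),
    ]
    return modes


def update_mode(members) -> ResponseVector:
    """Item-wise plurality level of the member vectors (lowest level on ties)."""
    codes = members if isinstance(members, np.ndarray) else encode_responses(members)
    if codes.shape[0] == 0:
        raise ValueError("cannot take the mode of an empty cluster")
    out = np.empty(10, dtype=np.int8)
    for j in range(10):
        counts = np.bincount(codes[:, j], minlength=int(N_LEVELS[j]))
        out[j] = counts.argmax()  # argmax returns the first (lowest) on ties
    return ResponseVector.from_codes(out)


def _distances(codes: np.ndarray, mode_codes: np.ndarray) -> np.ndarray:
    """(n, k) simple matching distances."""
    return (codes[:, None, :] != mode_codes[None, :, :]).sum(axis=2)


def _extract_codes(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        vectors = list(map(ResponseVector._make, zip(*(data[i] for i in ITEMS))))
        return encode_responses(vectors)
    if isinstance(data, np.ndarray):
        return data.astype(np.int8)
    return encode_responses(data)


def fit_kmodes(
    data,
    initial: list[ResponseVector] | None = None,
    max_iter: int = 100,
    seed=None,
) -> ClusterAssignment:
    """Batch k-modes on a survey table (or code matrix / ResponseVector list).

    ``seed`` is accepted for interface symmetry with the other stages; the
    batch algorithm with deterministic tie-breaks is fully deterministic,
    so it only matters if an empty-cluster reseed ever ties (it cannot:
    the farthest observation at the lowest index is chosen).
    """
    del seed
    codes = _extract_codes(data)
    n = codes.shape[0]
    if n == 0:
        raise ValueError("no respondents to cluster")
    modes = initial if initial is not None else default_initial_modes()
    mode_codes = np.array([m.to_codes() for m in modes])
    k = mode_codes.shape[0]
    if len({tuple(r) for r in mode_codes}) != k:
        raise ValueError("initial modes must be pairwise distinct")

    labels = np.full(n, -1)
    cost_history: list[int] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dist = _distances(codes, mode_codes)
        new_labels = dist.argmin(axis=1)  # ties -> lowest mode index
        cost = int(dist[np.arange(n), new_labels].sum())
        cost_history.append(cost)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for c in range(k):
            members = codes[labels == c]
            if members.shape[0] == 0:
                # reseed with the observation farthest from this cluster's mode
                far = int(_distances(codes, mode_codes[c : c + 1])[:, 0].argmax())
                mode_codes[c] = codes[far]
            else:
                mode_codes[c] = update_mode(members).to_codes()
    return ClusterAssignment(
        labels=labels + 1,
        modes=[ResponseVector.from_codes(r) for r in mode_codes],
        cost=cost_history[-1],
        n_iter=it,
        converged=converged,
        cost_history=cost_history,
    )
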