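"""Fuzzy c-means clustering of standardised stage profiles.

Each feature's per-stage mean expression is z-scored (population SD) so
clustering sees only the temporal shape, then partitioned by standard fuzzy
c-means with Euclidean distance:

    u_ij = d_ij^(-2/(m-1)) / sum_l d_il^(-2/(m-1))
    c_j  = sum_i u_ij^m x_i / sum_i u_ij^m

k defaults to 4, matching the four temporal patterns typical of staged bud
transcriptomes (up, down, and two transient peaks).  The fuzzifier m can be
set from the data by the Schwammle-Jensen rule.  Initialisation is
k-means++-style seeding from data rows under a fixed RNG; several restarts
are run and the best (lowest-objective) solution kept, so results are
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError

_EPS = 1e-12


@dataclass
class MembershipMatrix:
    """Fuzzy partition: memberships, centers and the converged objective."""

    feature_ids: list[str]
    u: np.ndarray                 # features x clusters, rows sum to 1
    centers: np.ndarray           # clusters x stages
    m: float
    objective: float
    n_iter: int
    objective_trace: list[float] = field(default_factory=list, repr=False)
    excluded: list[str] = field(default_factory=list)  # zero-variance rows

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.u, index=self.feature_ids, columns=cols)


def standardize(stage_means: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores with population SD; zero-variance rows are excluded.

    Returns the standardised frame and the list of excluded feature ids.
    """
    if stage_means.shape[1] < 2:
        raise ValidationError("standardize needs at least two stages")
    values = stage_means.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)      # population SD (ddof=0)
    flat = sd[:, 0] == 0
    excluded = list(stage_means.index[flat])
    kept = stage_means.index[~flat]
    z = (values[~flat] - mean[~flat]) / sd[~flat]
    return pd.DataFrame(z, index=kept, columns=stage_means.columns), excluded


def estimate_fuzzifier(X: np.ndarray | pd.DataFrame) -> float:
    """Schwammle-Jensen fuzzifier estimate from data dimensions, clipped to
    [1.05, 3]:  m = 1 + (1418/N + 22.05) D^-2
                  + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValidationError("need at least two features")
    m = (1.0 + (1418.0 / n + 22.05) * d ** -2.0
         + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134))
    return float(np.clip(m, 1.05, 3.0))


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact-hit rows get a crisp
    membership on the coincident center(s)."""
    hit = d2 <= _EPS
    u = np.zeros_like(d2)
    any_hit = hit.any(axis=1)
    if any_hit.any():
        h = hit[any_hit]
        u[any_hit] = h / h.sum(axis=1, keepdims=True)
    rest = ~any_hit
    if rest.any():
        w = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = w / w.sum(axis=1, keepdims=True)
    return u


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator
                   ) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(_sq_dists(X, np.asarray(centers)), axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


def fuzzy_cmeans(X: np.ndarray | pd.DataFrame, k: int = 4, m: float = 1.25,
                 tol: float = 1e-6, max_iter: int = 500, seed: int = 0,
                 n_init: int = 10) -> MembershipMatrix:
    """Fuzzy c-means with k-means++ seeding and restarts.

    The objective sum_ij u_ij^m d_ij^2 is asserted non-increasing across
    iterations; convergence is declared when the largest center coordinate
    shift falls below ``tol``.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.index)
        data = X.to_numpy(dtype=float)
    else:
        data = np.asarray(X, dtype=float)
        feature_ids = [str(i) for i in range(data.shape[0])]
    if k < 2:
        raise ValidationError("k must be at least 2")
    if m <= 1:
        raise ValidationError("fuzzifier m must exceed 1")
    if len(np.unique(data, axis=0)) < k:
        raise ValidationError("k exceeds the number of distinct rows")

    rng = np.random.default_rng(seed)
    best: MembershipMatrix | None = None
    for _ in range(n_init):
        centers = _kmeanspp_init(data, k, rng)
        prev_obj = np.inf
        trace: list[float] = []
        for it in range(1, max_iter + 1):
            d2 = _sq_dists(data, centers)
            u = _memberships(d2, m)
            um = u ** m
            obj = float((um * d2).sum())
            if obj > prev_obj + 1e-9 * max(1.0, abs(prev_obj)):
                raise AssertionError(
                    "fuzzy c-means objective increased "
                    f"({prev_obj:.6g} -> {obj:.6g})")
            prev_obj = obj
            trace.append(obj)
            new_centers = (um.T @ data) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                break
        d2 = _sq_dists(data, centers)
        u = _memberships(d2, m)
        obj = float((u ** m * d2).sum())
        trace.append(obj)
        if best is None or obj < best.objective:
            best = MembershipMatrix(
                feature_ids=feature_ids, u=u, centers=centers, m=m,
                objective=obj, n_iter=it, objective_trace=trace)
    return best


def assign_clusters(membership: MembershipMatrix, min_membership: float = 0.5
                    ) -> dict[str, int | None]:
    """Hard labels from the membership matrix.

    Argmax cluster (1-based) when its membership reaches
    ``min_membership``, else None (unassigned).  Ties go to the lowest
    cluster index.
    """
    out: dict[str, int | None] = {}
    for fid, row in zip(membership.feature_ids, membership.u):
        j = int(np.argmax(row))           # argmax takes the first = lowest
        out[fid] = j + 1 if row[j] >= min_membership else None
    return out
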