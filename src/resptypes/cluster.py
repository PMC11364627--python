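"""Ward clustering, gap-statistic model selection, and response-type profiles.

A *response type* is the centroid of one cluster of questionnaires in the
six-dimensional feature space (five main items + discrimination).  The number
of types is chosen with the gap statistic: the log within-cluster dispersion
of the data is compared, for each candidate k, against its expectation under
B structureless reference datasets drawn uniformly over the observed
per-feature ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .schema import DISCRIMINATION, ItemSchema, DEFAULT_SCHEMA


def _as_array(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    return X


def ward_linkage(features) -> np.ndarray:
    """Ward linkage matrix (scipy format) on Euclidean distances."""
    return linkage(_as_array(features), method="ward")


def ward_cluster(features, k: int, Z: np.ndarray | None = None) -> np.ndarray:
    """Cut a Ward agglomeration at k clusters; labels are 1..k.

    Each merge minimises the increase in total within-cluster sum of squared
    Euclidean distances.  ``Z`` may be passed to reuse a precomputed linkage.
    """
    X = _as_array(features)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    if k == 1:
        return np.ones(n, dtype=int)
    if k == n:
        return np.arange(1, n + 1)
    if Z is None:
        Z = ward_linkage(X)
    return fcluster(Z, t=k, criterion="maxclust")


def within_dispersion(features, labels) -> float:
    """Total within-cluster sum of squared distances to cluster centroids."""
    X = _as_array(features)
    labels = np.asarray(labels)
    W = 0.0
    for lab in np.unique(labels):
        member = X[labels == lab]
        if member.size == 0:
            raise ValueError(f"empty cluster label {lab}")
        W += float(((member - member.mean(axis=0)) ** 2).sum())
    return W


@dataclass
class GapCurve:
    """Gap-statistic curve over candidate cluster counts.

    gap_k = mean_b log W_k(ref_b) - log W_k(data); s_k is the reference
    standard deviation inflated by sqrt(1 + 1/B).  ``selected_k`` follows the
    one-standard-error rule (smallest k with gap_k >= gap_{k+1} - s_{k+1}),
    falling back to the argmax of the gap when no k qualifies.  The full
    curve is retained so an elbow can be inspected directly.
    """

    k_values: np.ndarray
    log_Wk: np.ndarray
    log_Wk_ref: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    B: int
    selected_k: int = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.k_values)
        if not (len(self.log_Wk) == len(self.gap) == len(self.s_k) == n):
            raise ValueError("curve arrays disagree in length")
        self.selected_k = self._select()

    def _select(self) -> int:
        for i in range(len(self.k_values) - 1):
            if self.gap[i] >= self.gap[i + 1] - self.s_k[i + 1]:
                return int(self.k_values[i])
        return int(self.k_values[int(np.argmax(self.gap))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "log_Wk": self.log_Wk,
                "log_Wk_ref": self.log_Wk_ref,
                "gap": self.gap,
                "s_k": self.s_k,
            }
        )


def gap_statistic(features, k_range, B: int = 50, seed: int = 0) -> GapCurve:
    """Gap statistic for Ward clustering over ``k_range``.

    References are drawn uniformly over the observed per-coordinate ranges
    (the simplest published reference distribution) and clustered with the
    same Ward procedure as the data.
    """
    X = _as_array(features)
    ks = sorted(int(k) for k in k_range)
    n = X.shape[0]
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 1 or ks[-1] >= n:
        raise ValueError(f"k_range must lie in [1, n) with n={n}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("degenerate feature: zero observed range")

    def log_wk_curve(data: np.ndarray) -> np.ndarray:
        Z = ward_linkage(data) if ks[-1] > 1 else None
        return np.array(
            [np.log(within_dispersion(data, ward_cluster(data, k, Z))) for k in ks]
        )

    log_wk = log_wk_curve(X)
    rng = np.random.default_rng(seed)
    ref = np.empty((B, len(ks)))
    for b in range(B):
        ref_data = rng.uniform(lo, hi, size=X.shape)
        ref[b] = log_wk_curve(ref_data)
    log_wk_ref = ref.mean(axis=0)
    gap = log_wk_ref - log_wk
    s_k = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(
        k_values=np.array(ks), log_Wk=log_wk, log_Wk_ref=log_wk_ref,
        gap=gap, s_k=s_k, B=B,
    )


def extract_profiles(
    features: pd.DataFrame, labels, schema: ItemSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Per-cluster mean +/- SD of each main item and of the discrimination.

    ``features`` should be the un-jittered six-dimensional features so the
    reported means are not noise-shifted.  Returns one row per cluster label
    with ``<item>_mean``, ``<item>_sd``, ``discrimination_mean``,
    ``discrimination_sd`` and ``size`` columns; sizes sum to n.
    """
    labels = np.asarray(labels)
    cols = list(schema.main_items) + [DISCRIMINATION]
    rows = {}
    for lab in np.unique(labels):
        member = features.loc[np.asarray(labels == lab), cols]
        row = {}
        for c in cols:
            row[f"{c}_mean"] = member[c].mean()
            row[f"{c}_sd"] = member[c].std(ddof=1) if len(member) > 1 else 0.0
        row["size"] = len(member)
        rows[int(lab)] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "type_id"
    out["size"] = out["size"].astype(int)
    return out


def order_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, dict[int, int]]:
    """Deterministically renumber profiles 1..k.

    Ordering is descending discrimination mean, ties broken by descending
    climate-change mean.  Returns the renumbered table and the old->new
    label mapping.
    """
    order = profiles.sort_values(
        ["discrimination_mean", "climate_change_mean"], ascending=[False, False]
    ).index
    mapping = {int(old): new for new, old in enumerate(order, start=1)}
    out = profiles.loc[order].copy()
    out.index = pd.Index(range(1, len(out) + 1), name="type_id")
    return out, mapping


def _centroids(profiles: pd.DataFrame, schema: ItemSchema) -> np.ndarray:
    cols = [f"{c}_mean" for c in list(schema.main_items) + [DISCRIMINATION]]
    return profiles[cols].to_numpy(dtype=float)


def match_profiles(
    profiles: pd.DataFrame,
    reference: pd.DataFrame,
    schema: ItemSchema = DEFAULT_SCHEMA,
) -> tuple[dict[int, int], dict[int, float]]:
    """Optimally assign extracted profiles to reference profiles.

    Minimises the total Euclidean distance between six-dimensional centroid
    vectors over all bijections (Hungarian assignment, not greedy).  Returns
    (mapping profile_id -> reference_id, per-profile distances).
    """
    if len(profiles) != len(reference):
        raise ValueError(
            f"profile count {len(profiles)} != reference count {len(reference)}"
        )
    A = _centroids(profiles, schema)
    Bc = _centroids(reference, schema)
    D = np.sqrt(((A[:, None, :] - Bc[None, :, :]) ** 2).sum(axis=2))
    ri, ci = linear_sum_assignment(D)
    mapping = {
        int(profiles.index[i]): int(reference.index[j]) for i, j in zip(ri, ci)
    }
    dists = {int(profiles.index[i]): float(D[i, j]) for i, j in zip(ri, ci)}
    return mapping, dists


def relabel(labels, mapping: dict[int, int]) -> np.ndarray:
    """Apply a cluster-id mapping to a label vector."""
    labels = np.asarray(labels)
    out = np.empty_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return out
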