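"""Country fingerprints, their distances, and the country dendrogram.

A country's *fingerprint* is the k-vector of proportions of each response
type among its respondents — a point on the probability simplex.  Countries
are compared by the Euclidean distance between fingerprints and summarised by
Ward agglomeration of the fingerprint vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import pdist, squareform

from .cluster import ward_linkage


def compute_fingerprints(
    labels, countries, k: int, min_country_n: int = 1
) -> pd.DataFrame:
    """Proportion of each response type per country.

    Entry (c, i) = #records of country c with label i / #records of country c.
    Countries with fewer than ``min_country_n`` respondents are excluded
    (the survey's minimum sample size per country); clustering itself is
    unaffected by the threshold.
    """
    labels = np.asarray(labels)
    countries = np.asarray(countries)
    if labels.shape != countries.shape:
        raise ValueError("labels and countries differ in length")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    codes = pd.unique(countries)
    rows, kept = [], []
    for c in codes:
        mask = countries == c
        n_c = int(mask.sum())
        if n_c == 0:
            raise ValueError(f"country {c!r} has zero records")
        if n_c < min_country_n:
            continue
        counts = np.bincount(labels[mask], minlength=k + 1)[1:]
        rows.append(counts / n_c)
        kept.append(c)
    out = pd.DataFrame(rows, index=pd.Index(kept, name="country"),
                       columns=range(1, k + 1))
    return out


def fingerprint_distance(fingerprints: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise Euclidean distances between fingerprints."""
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 countries")
    D = squareform(pdist(fingerprints.to_numpy(dtype=float)))
    return pd.DataFrame(D, index=fingerprints.index, columns=fingerprints.index)


@dataclass
class CountryTree:
    """Ward dendrogram over country fingerprints.

    ``Z`` is the scipy linkage matrix; ``leaves`` the country codes in input
    order.  Newick export places each internal node at half its merge height
    (ultrametric convention), so a two-country tree with merge height h is
    ``(A:h/2,B:h/2);``.
    """

    Z: np.ndarray
    leaves: list[str]

    def to_newick(self) -> str:
        root = to_tree(self.Z)

        def node_height(node) -> float:
            return 0.0 if node.is_leaf() else node.dist / 2.0

        def recurse(node, parent_height: float) -> str:
            length = parent_height - node_height(node)
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.12g}"
            h = node_height(node)
            left = recurse(node.left, h)
            right = recurse(node.right, h)
            return f"({left},{right}):{length:.12g}"

        h = node_height(root)
        left = recurse(root.left, h)
        right = recurse(root.right, h)
        return f"({left},{right});"


def country_dendrogram(fingerprints: pd.DataFrame) -> CountryTree:
    """Ward agglomeration of countries by their fingerprint vectors."""
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 countries")
    codes = list(fingerprints.index)
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate country codes")
    Z = ward_linkage(fingerprints.to_numpy(dtype=float))
    return CountryTree(Z=Z, leaves=codes)
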