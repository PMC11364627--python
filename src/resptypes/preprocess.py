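"""Questionnaire preprocessing: KNN imputation, feature engineering, jitter.

The pipeline order is impute -> engineer -> jitter.  Imputation operates on
the eight raw Likert items; the engineered representation is six-dimensional
(five main items plus the discrimination score); a small seeded Gaussian
perturbation then removes exact duplicates ahead of clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .schema import DEFAULT_SCHEMA, DISCRIMINATION, ItemSchema


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs.

    n_neighbors
        Neighbours averaged when imputing a missing item (default 8).
    jitter_variance
        Variance of the mean-zero Gaussian perturbation applied
        independently to every feature coordinate (default 0.001).
    seed
        Seed for the jitter stream.
    """

    n_neighbors: int = 8
    jitter_variance: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.jitter_variance < 0:
            raise ValueError("jitter_variance must be non-negative")


def impute_knn(
    matrix: pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
    schema: ItemSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Fill missing items with the average of the k nearest questionnaires.

    Closeness of two questionnaires is Euclidean distance over the items
    both observe, rescaled by sqrt(n_items / n_co-observed); each missing
    cell is the unweighted mean of that item over the ``n_neighbors``
    nearest records that observe it.  Observed cells are never altered.
    Imputed values are continuous (no re-rounding to the integer grid).
    """
    items = list(schema.items)
    X = matrix[items].to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (~obs).all(axis=1).any():
        row = int(np.argmax((~obs).all(axis=1)))
        raise ValueError(f"record {row} has all items missing; cannot impute")
    if X.shape[0] < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {config.n_neighbors + 1} records"
        )
    needs = ~obs.all(axis=0) & (obs.sum(axis=0) == 0)
    if needs.any():
        missing_items = [items[j] for j in np.flatnonzero(needs)]
        raise ValueError(f"no record observes item(s) {missing_items}")
    imputer = KNNImputer(n_neighbors=config.n_neighbors, weights="uniform")
    filled = imputer.fit_transform(X)
    out = matrix.copy()
    out[items] = filled
    return out


def engineer_features(
    matrix: pd.DataFrame, schema: ItemSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Replace the three minor items by the discrimination score.

    The discrimination D = mean(main items) - mean(minor items) measures how
    sharply a respondent separates real drivers from distractors; with items
    on a 1..5 scale it lies in [-4, 4].  Output columns are the five main
    items followed by ``discrimination`` (six dimensions).
    """
    main = matrix[list(schema.main_items)]
    minor = matrix[list(schema.minor_items)]
    if main.isna().any().any() or minor.isna().any().any():
        raise ValueError("feature engineering requires a complete (imputed) matrix")
    feats = main.copy()
    feats[DISCRIMINATION] = main.mean(axis=1) - minor.mean(axis=1)
    return feats


def jitter(
    features: pd.DataFrame, config: PreprocessConfig = PreprocessConfig()
) -> pd.DataFrame:
    """Add i.i.d. Gaussian(0, jitter_variance) noise to every coordinate.

    The perturbation exists to break exact duplicates (required for stable
    hierarchical clustering), not to change summaries; cluster profiles are
    computed on the un-jittered features.  One seeded stream is consumed in
    row-major order, so results are reproducible but depend on row order.
    """
    if config.jitter_variance == 0:
        return features.copy()
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, np.sqrt(config.jitter_variance), size=features.shape)
    return features + noise
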