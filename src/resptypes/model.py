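"""Model/Results interface for response-type fingerprinting.

``ResponseTypeModel`` holds a respondent table plus analysis settings;
``fit()`` runs impute -> engineer -> jitter -> (gap-select k) -> Ward
cluster and returns a ``ResponseTypeResults`` carrying labels, profiles,
the gap curve, country fingerprints and downstream methods (dendrogram,
index screen, summary table, plots).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import cluster as clu
from . import fingerprint as fp
from . import io as rio
from .preprocess import PreprocessConfig, engineer_features, impute_knn, jitter
from .schema import DEFAULT_SCHEMA, ItemSchema


class ResponseTypeModel:
    """Mixture-of-response-types analysis of a Likert questionnaire table.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per respondent: ``country`` plus the eight item columns
        (NaN = missing), as returned by :func:`resptypes.io.read_responses`
        or the synthetic generator.
    schema : ItemSchema
        Item roster (default: the biodiversity-driver roster).
    n_neighbors : int
        Neighbours for KNN imputation (default 8).
    jitter_variance : float
        Variance of the duplicate-breaking perturbation (default 0.001).
    k_range : iterable of int
        Candidate cluster counts for gap-statistic selection (default 2..12).
    n_reference : int
        Reference datasets B for the gap statistic (default 50).
    min_country_n : int
        Minimum respondents for a country to receive a fingerprint
        (default 25).
    seed : int
        Seed driving jitter and the gap references.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        schema: ItemSchema = DEFAULT_SCHEMA,
        *,
        n_neighbors: int = 8,
        jitter_variance: float = 0.001,
        k_range=range(2, 13),
        n_reference: int = 50,
        min_country_n: int = 25,
        seed: int = 0,
    ) -> None:
        self.data = data.reset_index(drop=True)
        self.schema = schema
        self.k_range = list(k_range)
        self.n_reference = n_reference
        self.min_country_n = min_country_n
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        jitter_seed, gap_seed = (int(s) for s in ss.generate_state(2) >> 1)
        self._gap_seed = gap_seed
        self.preprocess_config = PreprocessConfig(
            n_neighbors=n_neighbors,
            jitter_variance=jitter_variance,
            seed=jitter_seed,
        )

    @classmethod
    def from_csv(cls, path: str | Path, schema: ItemSchema = DEFAULT_SCHEMA, **kw):
        return cls(rio.read_responses(path, schema), schema, **kw)

    def preprocess(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Impute and engineer features; returns (features, jittered)."""
        imputed = impute_knn(self.data, self.preprocess_config, self.schema)
        features = engineer_features(imputed, self.schema)
        return features, jitter(features, self.preprocess_config)

    def fit(self, k: int | None = None) -> "ResponseTypeResults":
        """Cluster the questionnaires into response types.

        When ``k`` is None the number of types is selected with the gap
        statistic over ``k_range``; pass an integer to fix it.
        """
        features, jittered = self.preprocess()
        X = jittered.to_numpy(dtype=float)
        gap = None
        if k is None:
            gap = clu.gap_statistic(
                X, self.k_range, B=self.n_reference, seed=self._gap_seed
            )
            k = gap.selected_k
        Z = clu.ward_linkage(X)
        raw_labels = clu.ward_cluster(X, k, Z)
        profiles = clu.extract_profiles(features, raw_labels, self.schema)
        profiles, mapping = clu.order_profiles(profiles)
        labels = clu.relabel(raw_labels, mapping)
        return ResponseTypeResults(
            model=self, k=k, labels=labels, profiles=profiles,
            features=features, jittered=jittered, gap=gap, linkage=Z,
        )


class ResponseTypeResults:
    """Fitted response-type clustering and its country-level summaries.

    Attributes
    ----------
    k : int
        Number of response types.
    labels : ndarray
        Per-respondent type in 1..k (deterministic numbering: descending
        discrimination, ties by climate-change mean).
    profiles : DataFrame
        Per-type mean/SD of each main item and the discrimination, plus
        cluster size, computed on un-jittered features.
    gap : GapCurve or None
        Model-selection curve when k was selected automatically.
    fingerprints : DataFrame
        Country x type proportion matrix (countries below the minimum
        sample size excluded).
    """

    def __init__(self, model, k, labels, profiles, features, jittered, gap, linkage):
        self.model = model
        self.k = int(k)
        self.labels = labels
        self.profiles = profiles
        self.features = features
        self.jittered = jittered
        self.gap = gap
        self.linkage = linkage
        countries = model.data["country"].to_numpy()
        small = (
            pd.Series(countries).value_counts() < model.min_country_n
        )
        excluded = sorted(small[small].index)
        if excluded:
            warnings.warn(
                f"countries below the minimum sample size "
                f"(n < {model.min_country_n}) excluded from fingerprints: "
                f"{excluded}",
                UserWarning,
                stacklevel=2,
            )
        self.excluded_countries = excluded
        self.fingerprints = fp.compute_fingerprints(
            labels, countries, self.k, min_country_n=model.min_country_n
        )

    # -- country-level views -------------------------------------------------

    def distance_matrix(self) -> pd.DataFrame:
        """Euclidean distances between country fingerprints."""
        return fp.fingerprint_distance(self.fingerprints)

    def country_tree(self) -> fp.CountryTree:
        """Ward dendrogram over country fingerprints."""
        return fp.country_dendrogram(self.fingerprints)

    def correlate(self, index_table: pd.DataFrame, **kw) -> pd.DataFrame:
        """Spearman screen of fingerprint components against indices."""
        return assoc.correlate_fingerprints(self.fingerprints, index_table, **kw)

    def match_to(self, reference_profiles: pd.DataFrame):
        """Optimal assignment of fitted profiles to reference profiles."""
        return clu.match_profiles(self.profiles, reference_profiles, self.model.schema)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Response-type clustering",
            "=" * 60,
            f"respondents: {len(self.labels)}    "
            f"countries: {self.model.data['country'].nunique()} "
            f"({len(self.fingerprints)} fingerprinted)",
            f"response types (k): {self.k}"
            + (
                f"   [gap statistic over k={self.model.k_range[0]}"
                f"..{self.model.k_range[-1]}, B={self.gap.B}]"
                if self.gap is not None
                else "   [fixed]"
            ),
        ]
        if self.excluded_countries:
            lines.append(
                f"excluded (n < {self.model.min_country_n}): "
                + ", ".join(self.excluded_countries)
            )
        lines.append("")
        show = self.profiles.copy()
        mean_cols = [c for c in show.columns if c.endswith("_mean")]
        sd_cols = [c for c in show.columns if c.endswith("_sd")]
        tidy = pd.DataFrame(index=show.index)
        for m, s in zip(mean_cols, sd_cols):
            name = m[: -len("_mean")]
            tidy[name] = [
                f"{mv:.2f} ± {sv:.2f}" for mv, sv in zip(show[m], show[s])
            ]
        tidy["size"] = show["size"]
        lines.append(tidy.to_string())
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write profiles, gap curve, fingerprints, distances and tree."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["profiles"] = outdir / "profiles.csv"
        self.profiles.to_csv(paths["profiles"], float_format="%.12g")
        if self.gap is not None:
            paths["gap_curve"] = outdir / "gap_curve.csv"
            self.gap.to_frame().to_csv(paths["gap_curve"], index=False,
                                       float_format="%.12g")
        paths["fingerprints"] = outdir / "fingerprints.csv"
        rio.write_fingerprints(self.fingerprints, paths["fingerprints"])
        if len(self.fingerprints) >= 2:
            paths["distances"] = outdir / "distances.csv"
            self.distance_matrix().to_csv(paths["distances"], float_format="%.12g")
            paths["tree"] = outdir / "country_tree.nwk"
            paths["tree"].write_text(self.country_tree().to_newick() + "\n")
        return paths

    # -- plotting ------------------------------------------------------------

    def plot_gap(self, ax=None):
        """Scree plot of the gap curve with one-SE error bars."""
        if self.gap is None:
            raise ValueError("no gap curve: k was fixed by the caller")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.gap
        ax.errorbar(g.k_values, g.gap, yerr=g.s_k, marker="o", capsize=3)
        ax.axvline(g.selected_k, ls="--", color="grey")
        ax.set_xlabel("number of response types k")
        ax.set_ylabel("gap statistic")
        return ax

    def plot_country_tree(self, ax=None):
        """Dendrogram of countries by fingerprint distance."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        tree = self.country_tree()
        dendrogram(tree.Z, labels=tree.leaves, ax=ax)
        ax.set_ylabel("Ward merge height")
        return ax
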