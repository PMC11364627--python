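"""End-to-end orchestration with file-based stages and a run log.

Each stage reads and writes delimited text, so a run can be resumed from any
intermediate artefact with identical results; ``run_pipeline`` simply chains
the stages.  All randomness (jitter, gap references, simulation) derives
from one pipeline seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import cluster as clu
from . import fingerprint as fp
from . import io as rio
from .preprocess import PreprocessConfig, engineer_features, impute_knn, jitter
from .schema import DEFAULT_SCHEMA, DISCRIMINATION
from .simulate import GeneratorConfig, sample_index, sample_questionnaires

#: per-index (component type, target Spearman rho) used by ``simulate`` —
#: mirrors the strongest published association of each index
DEFAULT_INDEX_TARGETS = {
    "CO2": (1, 0.458),
    "EPI": (3, -0.445),
    "GBI": (5, 0.468),
    "NIS": (7, -0.516),
    "LPI": (6, 0.487),
}

_FEATURE_COLS = list(DEFAULT_SCHEMA.main_items) + [DISCRIMINATION]


@dataclass
class PipelineConfig:
    """Settings for a full analysis run."""

    responses: str
    outdir: str
    indices: str | None = None
    n_neighbors: int = 8
    jitter_variance: float = 0.001
    k: int | None = None
    k_min: int = 2
    k_max: int = 12
    n_reference: int = 50
    min_country_n: int = 25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _log_line(log: list, stage: str, **info) -> None:
    log.append({"stage": stage, **info})


def _write_log(log: list, outdir: Path) -> None:
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def _derived_seeds(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    a, b = (int(s) for s in ss.generate_state(2) >> 1)
    return a, b


def stage_preprocess(config: PipelineConfig) -> tuple[Path, Path]:
    """responses.csv -> features.csv (un-jittered) + features_jittered.csv."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = rio.read_responses(config.responses)
    jitter_seed, _ = _derived_seeds(config.seed)
    pcfg = PreprocessConfig(
        n_neighbors=config.n_neighbors,
        jitter_variance=config.jitter_variance,
        seed=jitter_seed,
    )
    imputed = impute_knn(data, pcfg)
    features = engineer_features(imputed)
    jittered = jitter(features, pcfg)
    for df, name in ((features, "features.csv"), (jittered, "features_jittered.csv")):
        out = df.copy()
        out.insert(0, "country", data["country"])
        out.to_csv(outdir / name, index=False, float_format="%.12g")
    return outdir / "features.csv", outdir / "features_jittered.csv"


def stage_cluster(config: PipelineConfig) -> tuple[Path, Path, Path | None]:
    """features -> labels.csv + profiles.csv (+ gap_curve.csv)."""
    outdir = Path(config.outdir)
    features = pd.read_csv(outdir / "features.csv")
    jittered = pd.read_csv(outdir / "features_jittered.csv")
    X = jittered[_FEATURE_COLS].to_numpy(dtype=float)
    _, gap_seed = _derived_seeds(config.seed)
    gap_path = None
    k = config.k
    if k is None:
        gap = clu.gap_statistic(
            X, range(config.k_min, config.k_max + 1),
            B=config.n_reference, seed=gap_seed,
        )
        gap.to_frame().to_csv(outdir / "gap_curve.csv", index=False,
                              float_format="%.12g")
        gap_path = outdir / "gap_curve.csv"
        k = gap.selected_k
    labels = clu.ward_cluster(X, k)
    profiles = clu.extract_profiles(features[_FEATURE_COLS], labels)
    profiles, mapping = clu.order_profiles(profiles)
    labels = clu.relabel(labels, mapping)
    lab = pd.DataFrame({"country": features["country"], "label": labels})
    lab.to_csv(outdir / "labels.csv", index=False)
    profiles.to_csv(outdir / "profiles.csv", float_format="%.12g")
    return outdir / "labels.csv", outdir / "profiles.csv", gap_path


def stage_fingerprint(config: PipelineConfig) -> tuple[Path, Path | None, Path | None]:
    """labels.csv -> fingerprints.csv + distances.csv + country_tree.nwk."""
    outdir = Path(config.outdir)
    lab = pd.read_csv(outdir / "labels.csv")
    k = int(lab["label"].max())
    fps = fp.compute_fingerprints(
        lab["label"].to_numpy(), lab["country"].to_numpy(), k,
        min_country_n=config.min_country_n,
    )
    rio.write_fingerprints(fps, outdir / "fingerprints.csv")
    dist_path = tree_path = None
    if len(fps) >= 2:
        fp.fingerprint_distance(fps).to_csv(
            outdir / "distances.csv", float_format="%.12g"
        )
        dist_path = outdir / "distances.csv"
        tree_path = outdir / "country_tree.nwk"
        tree_path.write_text(fp.country_dendrogram(fps).to_newick() + "\n")
    return outdir / "fingerprints.csv", dist_path, tree_path


def stage_correlate(config: PipelineConfig) -> Path:
    """fingerprints.csv + index table -> associations.csv."""
    outdir = Path(config.outdir)
    if config.indices is None:
        raise ValueError("no index table configured")
    fps = rio.read_fingerprints(outdir / "fingerprints.csv")
    idx = rio.read_index_table(config.indices)
    cells = assoc.correlate_fingerprints(fps, idx)
    rio.write_correlations(cells, outdir / "associations.csv")
    return outdir / "associations.csv"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run read -> impute -> engineer -> jitter -> select k -> cluster ->
    profiles -> fingerprints -> dendrogram -> correlations, logging each
    stage; returns the artefact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    artefacts: dict = {"outdir": str(outdir)}
    _log_line(log, "config", seed=config.seed,
              settings={k: v for k, v in vars(config).items()})
    stage = "preprocess"
    try:
        f_path, fj_path = stage_preprocess(config)
        n = len(pd.read_csv(f_path))
        _log_line(log, "preprocess", rows=n, seed=config.seed)
        artefacts["features"] = str(f_path)

        stage = "cluster"
        labels_path, profiles_path, gap_path = stage_cluster(config)
        profiles = pd.read_csv(profiles_path)
        _log_line(log, "cluster", rows=n, k=len(profiles))
        artefacts.update(
            labels=str(labels_path), profiles=str(profiles_path),
            gap_curve=None if gap_path is None else str(gap_path),
        )

        stage = "fingerprint"
        fp_path, dist_path, tree_path = stage_fingerprint(config)
        fps = rio.read_fingerprints(fp_path)
        lab = pd.read_csv(labels_path)
        dropped = sorted(set(lab["country"].str.upper()) - set(fps.index))
        _log_line(log, "fingerprint", countries=len(fps),
                  excluded_below_min_n=dropped)
        artefacts.update(
            fingerprints=str(fp_path),
            distances=None if dist_path is None else str(dist_path),
            tree=None if tree_path is None else str(tree_path),
        )

        if config.indices is not None:
            stage = "correlate"
            cells_path = stage_correlate(config)
            cells = pd.read_csv(cells_path)
            _log_line(log, "correlate", cells=len(cells),
                      flagged=int((cells["moderate"] & cells["significant"]).sum()))
            artefacts["associations"] = str(cells_path)
    except Exception as exc:  # annotate failures with the failing stage
        _log_line(log, "error", stage_failed=stage, message=str(exc))
        _write_log(log, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_log(log, outdir)
    artefacts["log"] = str(outdir / "run_log.json")
    return artefacts


def simulate_files(
    config: GeneratorConfig,
    outdir: str | Path,
    index_targets: dict[str, tuple[int, float]] | None = None,
) -> dict:
    """Write a synthetic respondent CSV, index CSV and truth files.

    The index CSV is only produced for configs with at least 5 countries
    (Spearman needs variation across countries); truth files carry the
    generating labels and fingerprints for evaluation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, labels = sample_questionnaires(config)
    rio.write_responses(matrix, outdir / "responses.csv")
    truth = pd.DataFrame({"country": matrix["country"], "label": labels})
    truth.to_csv(outdir / "truth_labels.csv", index=False)
    fps = pd.DataFrame(
        {c: config.country_fingerprints[c] for c in sorted(config.country_fingerprints)},
        index=range(1, config.k + 1),
    ).T
    fps.index.name = "country"
    rio.write_fingerprints(fps, outdir / "truth_fingerprints.csv")
    artefacts = {
        "responses": str(outdir / "responses.csv"),
        "truth_labels": str(outdir / "truth_labels.csv"),
        "truth_fingerprints": str(outdir / "truth_fingerprints.csv"),
    }
    if len(fps) >= 5:
        if index_targets is None:
            index_targets = DEFAULT_INDEX_TARGETS
        seeds = np.random.SeedSequence(config.seed).generate_state(
            len(index_targets) + 1
        )[1:] >> 1
        idx = pd.DataFrame(index=fps.index)
        for (name, (type_id, rho)), s in zip(index_targets.items(), seeds):
            idx[name] = sample_index(fps[type_id], rho, seed=int(s))
        rio.write_index_table(idx, outdir / "indices.csv")
        artefacts["indices"] = str(outdir / "indices.csv")
    return artefacts
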