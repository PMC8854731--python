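"""End-to-end orchestration: recordings -> features -> decoding -> importance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoding import (
    ClassificationEvaluation,
    LabeledDataset,
    RegressionEvaluation,
    crossval_experiment,
    make_folds,
)
from .joint_importance import (
    JointImportanceProfile,
    importance_profile,
    profiles_to_frame,
    reduce_pairs,
)
from .kinematics import (
    derive_joints,
    to_local_coordinates,
    velocity_butterworth,
    velocity_savgol,
)
from .mocap_io import MarkerJointMap, MarkerRecording, fill_gaps, read_marker_recording, trim_to_window
from .movement_features import (
    DEFAULT_SIGMA,
    correntropy_matrix,
    feature_pair_index,
    features_to_frame,
    frame_to_feature_matrix,
    vectorize_lower,
)

__all__ = [
    "FeatureOptions",
    "DecodingOptions",
    "extract_features",
    "features_from_recordings",
    "load_recordings_dir",
    "build_dataset",
    "decode_and_attribute",
    "evaluations_to_frame",
    "run_manifest",
]


@dataclass
class FeatureOptions:
    source_kind: str = "position"  # position | velocity
    sigma: float = DEFAULT_SIGMA
    trim_window: tuple[float, float] | None = None  # seconds
    velocity_filter: str = "butterworth"  # butterworth | savgol
    butterworth_cutoff_hz: float = 24.0
    butterworth_order: int = 2
    savgol_window: int = 7
    savgol_polyorder: int = 2
    rotation_mode: str = "per_frame"
    max_gap_frames: int = 10


@dataclass
class DecodingOptions:
    targets: list[str] = field(default_factory=lambda: ["gender"])
    families: list[str] = field(default_factory=lambda: ["svm"])
    k: int = 5
    seed: int = 0
    split: str = "random"  # random | grouped


def extract_features(
    rec: MarkerRecording, jmap: MarkerJointMap, opts: FeatureOptions | None = None
):
    """Single-recording pipeline returning the FeatureVector."""
    opts = opts or FeatureOptions()
    if rec.missing_mask.any():
        rec = fill_gaps(rec, opts.max_gap_frames)
    if opts.trim_window is not None:
        rec = trim_to_window(rec, *opts.trim_window)
    jrec = to_local_coordinates(derive_joints(rec, jmap), jmap, opts.rotation_mode)
    if opts.source_kind == "velocity":
        if opts.velocity_filter == "butterworth":
            jrec = velocity_butterworth(jrec, opts.butterworth_cutoff_hz, opts.butterworth_order)
        elif opts.velocity_filter == "savgol":
            jrec = velocity_savgol(jrec, opts.savgol_window, opts.savgol_polyorder)
        else:
            raise ValueError(f"unknown velocity filter {opts.velocity_filter!r}")
    elif opts.source_kind != "position":
        raise ValueError(f"unknown source_kind {opts.source_kind!r}")
    return vectorize_lower(correntropy_matrix(jrec, sigma=opts.sigma))


def features_from_recordings(
    recordings, jmap: MarkerJointMap, opts: FeatureOptions | None = None
) -> pd.DataFrame:
    """Feature table over an iterable of recordings; errors name the sample."""
    vectors = []
    for rec in recordings:
        try:
            vectors.append(extract_features(rec, jmap, opts))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for participant={rec.participant_id!r} "
                f"stimulus={rec.stimulus_id!r}: {exc}"
            ) from exc
    return features_to_frame(vectors)


def load_recordings_dir(path, expected_rate: float | None = None) -> list[MarkerRecording]:
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv recordings under {path}")
    return [read_marker_recording(f, expected_rate=expected_rate) for f in files]


def build_dataset(features_df: pd.DataFrame, labels: pd.DataFrame) -> LabeledDataset:
    X, ids = frame_to_feature_matrix(features_df)
    labels = labels.copy()
    labels.index = labels.index.astype(str)
    return LabeledDataset(features=X, sample_ids=ids, labels=labels)


def decode_and_attribute(
    data: LabeledDataset,
    jmap: MarkerJointMap,
    opts: DecodingOptions,
    dataset_tag: str = "",
):
    """Run every (target, family) experiment; returns (evaluations, profiles, models).

    Profiles come in both granularities for each experiment.
    """
    groups = data.participants if opts.split == "grouped" else None
    folds = make_folds(data.n_samples, k=opts.k, seed=opts.seed, groups=groups)
    pair_index = feature_pair_index(_feature_dim(data.features.shape[1]))
    evaluations, profiles, all_models = [], [], {}
    for target in opts.targets:
        for family in opts.families:
            if (family == "svm") != (target == "gender"):
                continue  # svm <-> gender only; regression for the rest
            evaluation, models = crossval_experiment(data, target, family, folds)
            evaluations.append(evaluation)
            all_models[(target, family)] = models
            full = importance_profile(
                models,
                pair_index,
                jmap.joint_labels,
                target_name=target,
                dataset_tag=dataset_tag,
            )
            profiles.append(full)
            profiles.append(reduce_pairs(full, jmap))
    return evaluations, profiles, all_models


def _feature_dim(n_features: int) -> int:
    # invert F = D(D-1)/2
    D = int(round((1 + np.sqrt(1 + 8 * n_features)) / 2))
    if D * (D - 1) // 2 != n_features:
        raise ValueError(f"{n_features} is not a triangular number")
    return D


def evaluations_to_frame(evaluations) -> pd.DataFrame:
    """Tidy (target, family, fold, metric, value) table."""
    rows = []
    for ev in evaluations:
        if isinstance(ev, RegressionEvaluation):
            for f, (r2, rmse) in enumerate(zip(ev.per_fold_r2, ev.per_fold_rmse)):
                rows.append((ev.target_name, ev.family, f, "r2", r2))
                rows.append((ev.target_name, ev.family, f, "rmse", rmse))
            rows.append((ev.target_name, ev.family, -1, "mean_r2", ev.mean_r2))
            rows.append((ev.target_name, ev.family, -1, "mean_rmse", ev.mean_rmse))
        elif isinstance(ev, ClassificationEvaluation):
            for f, acc in enumerate(ev.per_fold_accuracy):
                rows.append((ev.target_name, ev.family, f, "accuracy", acc))
            rows.append((ev.target_name, ev.family, -1, "mean_accuracy", ev.mean_accuracy))
        else:
            raise TypeError(f"unknown evaluation type {type(ev)}")
    return pd.DataFrame(rows, columns=["target", "family", "fold", "metric", "value"])


def run_manifest(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }
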