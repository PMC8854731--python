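"""Joint importance: mapping linear-model weights back onto joints.

Every feature element links two coordinate dimensions and thereby one
or two joints.  Summing the absolute weights of all elements touching
a joint, across all cross-validation folds, gives a raw per-joint
score; min-max normalization yields the length-20 importance vector,
and averaging left/right pairs reduces it to 12 entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import TrainedLinearModel
from .mocap_io import MarkerJointMap

__all__ = [
    "JointImportanceProfile",
    "accumulate_importance",
    "minmax_normalize",
    "reduce_pairs",
    "importance_profile",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass
class JointImportanceProfile:
    joint_labels: list[str]
    values: np.ndarray  # min-max normalized, in [0, 1]
    raw_sums: np.ndarray  # pre-normalization absolute-weight sums
    granularity: str  # full20 | paired12
    target_name: str = ""
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.raw_sums = np.asarray(self.raw_sums, dtype=float)
        if len(self.joint_labels) != self.values.size != self.raw_sums.size:
            raise ValueError("labels, values and raw_sums must align")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("normalized values must lie in [0, 1]")


def accumulate_importance(
    models: list[TrainedLinearModel],
    pair_index: pd.DataFrame,
    n_joints: int,
) -> np.ndarray:
    """Sum |weight| onto each endpoint joint, over all elements and folds.

    An element whose two dimensions belong to the same joint contributes
    its magnitude once to that joint.
    """
    ji = pair_index["joint_i"].to_numpy()
    jj = pair_index["joint_j"].to_numpy()
    raw = np.zeros(n_joints)
    for model in models:
        w = np.abs(np.asarray(model.weights, dtype=float))
        if w.size != len(pair_index):
            raise ValueError(
                f"model has {w.size} weights but pair index has {len(pair_index)} elements"
            )
        np.add.at(raw, ji, w)
        off = ji != jj
        np.add.at(raw, jj[off], w[off])
    return raw


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Affine map onto [0, 1]; a constant vector maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(raw).all():
        raise ValueError("non-finite input")
    span = raw.max() - raw.min()
    if span == 0:
        return np.zeros_like(raw)
    return (raw - raw.min()) / span


def importance_profile(
    models: list[TrainedLinearModel],
    pair_index: pd.DataFrame,
    joint_labels: list[str],
    target_name: str = "",
    dataset_tag: str = "",
) -> JointImportanceProfile:
    """Full-granularity (length-20) profile from per-fold models."""
    raw = accumulate_importance(models, pair_index, len(joint_labels))
    return JointImportanceProfile(
        joint_labels=list(joint_labels),
        values=minmax_normalize(raw),
        raw_sums=raw,
        granularity="full20",
        target_name=target_name,
        dataset_tag=dataset_tag,
    )


def reduce_pairs(
    profile: JointImportanceProfile,
    jmap: MarkerJointMap,
    average_normalized: bool = False,
) -> JointImportanceProfile:
    """Average left/right pair groups down to the 12-joint profile.

    By default groups average the raw sums and the 12-vector is then
    min-max normalized; ``average_normalized`` instead averages the
    already-normalized 20-joint values before renormalizing.  Because
    min-max normalization is affine the two orders produce identical
    profiles; the flag exists only to make the chosen order explicit.
    """
    if profile.granularity != "full20":
        raise ValueError("pair reduction starts from a full-granularity profile")
    idx = {j: i for i, j in enumerate(profile.joint_labels)}
    source = profile.values if average_normalized else profile.raw_sums
    group_vals = []
    for group, members in jmap.pair_groups.items():
        try:
            rows = [idx[j] for j in members]
        except KeyError as exc:
            raise ValueError(f"pair group {group!r} references unknown joint {exc}") from exc
        group_vals.append(float(np.mean(source[rows])))
    group_vals = np.asarray(group_vals)
    return JointImportanceProfile(
        joint_labels=jmap.group_labels,
        values=minmax_normalize(group_vals),
        raw_sums=group_vals,
        granularity="paired12",
        target_name=profile.target_name,
        dataset_tag=profile.dataset_tag,
    )


def profiles_to_frame(profiles: list[JointImportanceProfile]) -> pd.DataFrame:
    """Tidy long-format table: one row per (profile, joint)."""
    rows = []
    for p in profiles:
        for joint, raw, val in zip(p.joint_labels, p.raw_sums, p.values):
            rows.append(
                {
                    "dataset_tag": p.dataset_tag,
                    "target_name": p.target_name,
                    "granularity": p.granularity,
                    "joint": joint,
                    "raw_sum": raw,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[JointImportanceProfile]:
    profiles = []
    for (tag, target, gran), grp in df.groupby(
        ["dataset_tag", "target_name", "granularity"], sort=False, dropna=False
    ):
        profiles.append(
            JointImportanceProfile(
                joint_labels=grp["joint"].tolist(),
                values=grp["value"].to_numpy(dtype=float),
                raw_sums=grp["raw_sum"].to_numpy(dtype=float),
                granularity=str(gran),
                target_name="" if pd.isna(target) else str(target),
                dataset_tag="" if pd.isna(tag) else str(tag),
            )
        )
    return profiles
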