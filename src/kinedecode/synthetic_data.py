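"""Seeded synthetic dance cohorts with known ground truth.

Each dancer's markers follow rest positions on a template skeleton plus
a sum of seeded oscillators (0.5-4 Hz).  Inter-joint coupling is
implemented through shared oscillator phases: markers belonging to a
target's joint subset draw their phases close to a stimulus-wide shared
phase, with a coupling coefficient that increases with the dancer's
label value.  Gender additionally scales the skeleton.  Preference
scores are affine in the traits plus noise, so preference information
reaches the kinematics only through the traits.

All randomness derives from the single spec seed via
``numpy.random.SeedSequence`` sub-keys, making every artifact
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import GENRE_NAMES, TRAIT_NAMES
from .mocap_io import MarkerJointMap, MarkerRecording, default_marker_joint_map, write_marker_recording

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "default_trait_joint_sets",
    "default_preference_loadings",
    "sample_cohort_labels",
    "synthesize_recording",
    "generate_cohort",
    "write_cohort",
]

# template skeleton: marker -> rest position (ml, ap, vertical), millimetres
_SKELETON: dict[str, tuple[float, float, float]] = {
    "hip_back_left": (-80.0, -120.0, 1010.0),
    "hip_back_right": (80.0, -120.0, 1010.0),
    "hip_left": (-130.0, 0.0, 1000.0),
    "hip_right": (130.0, 0.0, 1000.0),
    "shoulder_left": (-190.0, 0.0, 1450.0),
    "shoulder_right": (190.0, 0.0, 1450.0),
    "head_front": (0.0, 80.0, 1700.0),
    "head_left": (-80.0, 0.0, 1700.0),
    "head_right": (80.0, 0.0, 1700.0),
    "elbow_left": (-280.0, 0.0, 1200.0),
    "elbow_right": (280.0, 0.0, 1200.0),
    "wrist_left": (-330.0, 80.0, 1000.0),
    "wrist_right": (330.0, 80.0, 1000.0),
    "finger_left": (-350.0, 120.0, 900.0),
    "finger_right": (350.0, 120.0, 900.0),
    "knee_left": (-140.0, 30.0, 550.0),
    "knee_right": (140.0, 30.0, 550.0),
    "ankle_left": (-140.0, -20.0, 100.0),
    "ankle_right": (140.0, -20.0, 100.0),
    "toe_left": (-140.0, 120.0, 20.0),
    "toe_right": (140.0, 120.0, 20.0),
}

# movement amplitude scale per marker (mm): limbs move more than the core
_AMPLITUDE: dict[str, float] = {
    "hip_back_left": 60.0,
    "hip_back_right": 60.0,
    "hip_left": 70.0,
    "hip_right": 70.0,
    "shoulder_left": 120.0,
    "shoulder_right": 120.0,
    "head_front": 110.0,
    "head_left": 110.0,
    "head_right": 110.0,
    "elbow_left": 220.0,
    "elbow_right": 220.0,
    "wrist_left": 300.0,
    "wrist_right": 300.0,
    "finger_left": 340.0,
    "finger_right": 340.0,
    "knee_left": 150.0,
    "knee_right": 150.0,
    "ankle_left": 190.0,
    "ankle_right": 190.0,
    "toe_left": 210.0,
    "toe_right": 210.0,
}


def default_trait_joint_sets() -> dict[str, list[str]]:
    """Disjoint informative joint subsets, one per trait plus gender."""
    return {
        "gender": ["left_shoulder", "right_shoulder", "left_hip", "right_hip"],
        "openness": ["head", "left_wrist", "right_wrist"],
        "conscientiousness": ["left_knee", "right_knee"],
        "extraversion": ["left_elbow", "right_elbow"],
        "agreeableness": ["left_ankle", "right_ankle"],
        "neuroticism": ["left_finger", "right_finger"],
    }


def default_preference_loadings() -> np.ndarray:
    """12 x 5 loadings of genre preferences on traits (rows follow GENRE_NAMES)."""
    L = np.zeros((len(GENRE_NAMES), len(TRAIT_NAMES)))
    # each genre loads mostly on one or two traits
    assignments = {
        "blues": {"openness": 0.9},
        "country": {"agreeableness": 0.9},
        "dance": {"extraversion": 0.9},
        "jazz": {"openness": 0.7, "conscientiousness": 0.4},
        "metal": {"neuroticism": 0.8, "agreeableness": -0.4},
        "pop": {"extraversion": 0.7, "agreeableness": 0.4},
        "rap": {"extraversion": 0.5, "openness": -0.5},
        "reggae": {"openness": 0.5, "agreeableness": 0.5},
        "rock": {"openness": 0.6, "neuroticism": 0.4},
        "soul": {"agreeableness": 0.6, "openness": 0.4},
        "funk": {"extraversion": 0.6, "openness": 0.4},
        "oldie": {"conscientiousness": 0.9},
    }
    for g, loads in assignments.items():
        for t, v in loads.items():
            L[GENRE_NAMES.index(g), TRAIT_NAMES.index(t)] = v
    return L


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort; every default is desk-scale."""

    n_dancers: int = 60
    female_fraction: float = 0.7
    n_stimuli: int = 4
    duration: float = 30.0  # seconds
    sampling_rate: float = 60.0  # Hz
    trait_joint_sets: dict[str, list[str]] = field(default_factory=default_trait_joint_sets)
    effect_size: float = 0.8  # coupling swing per unit label range
    gender_effect: float = 1.0  # skeleton scale + coupling offset
    base_coupling: float = 0.5
    noise_sd: float = 10.0  # mm
    preference_loadings: np.ndarray = field(default_factory=default_preference_loadings)
    preference_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dancers < 1 or self.n_stimuli < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.duration * self.sampling_rate < 2:
            raise ValueError("duration x rate must give at least 2 frames")
        if self.effect_size < 0 or self.gender_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        self.preference_loadings = np.asarray(self.preference_loadings, dtype=float)
        if self.preference_loadings.shape != (len(GENRE_NAMES), len(TRAIT_NAMES)):
            raise ValueError("preference_loadings must be 12 x 5")
        jmap = default_marker_joint_map()
        known = set(jmap.joint_labels)
        for target, joints in self.trait_joint_sets.items():
            unknown = set(joints) - known
            if unknown:
                raise ValueError(f"target {target!r} references unknown joints {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    labels: pd.DataFrame  # indexed by participant id
    recordings: dict[tuple[str, str], MarkerRecording]
    ground_truth: dict  # target -> informative joints / pair groups
    marker_joint_map: MarkerJointMap


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def sample_cohort_labels(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Gender, five traits in [1, 5], twelve preferences in [1, 7]."""
    rng = _rng(spec.seed, 11)
    pids = [f"P{i:03d}" for i in range(spec.n_dancers)]
    female = rng.random(spec.n_dancers) < spec.female_fraction
    traits = rng.uniform(1.0, 5.0, size=(spec.n_dancers, len(TRAIT_NAMES)))
    noise = rng.normal(0.0, spec.preference_noise_sd, size=(spec.n_dancers, len(GENRE_NAMES)))
    prefs = np.clip(4.0 + (traits - 3.0) @ spec.preference_loadings.T + noise, 1.0, 7.0)
    df = pd.DataFrame(
        {"gender": np.where(female, "female", "male")},
        index=pd.Index(pids, name="participant_id"),
    )
    for k, t in enumerate(TRAIT_NAMES):
        df[t] = traits[:, k]
    for k, g in enumerate(GENRE_NAMES):
        df[g] = prefs[:, k]
    return df


def _marker_targets(spec: SyntheticCohortSpec, jmap: MarkerJointMap) -> dict[str, list[str]]:
    """Expand each target's joint subset to the markers defining those joints."""
    out = {}
    for target, joints in spec.trait_joint_sets.items():
        markers: list[str] = []
        for j in joints:
            for m in jmap.joint_definitions[j]:
                if m not in markers:
                    markers.append(m)
        out[target] = markers
    return out


def _coupling_coefficients(
    spec: SyntheticCohortSpec, dancer_labels: pd.Series, jmap: MarkerJointMap
) -> dict[str, float]:
    """Per-marker phase-coupling coefficient in [0, 1] for one dancer."""
    coeff = {m: spec.base_coupling for m in _SKELETON}
    is_female = str(dancer_labels["gender"]) == "female"
    for target, markers in _marker_targets(spec, jmap).items():
        if target == "gender":
            c = spec.base_coupling + 0.2 * spec.gender_effect * (1.0 if is_female else -1.0)
        else:
            value = float(dancer_labels[target])  # trait in [1,5], midpoint 3
            c = spec.base_coupling + spec.effect_size * (value - 3.0) / 4.0
        for m in markers:
            coeff[m] = float(np.clip(c, 0.0, 1.0))
    return coeff


def synthesize_recording(
    dancer_labels: pd.Series,
    spec: SyntheticCohortSpec,
    stimulus_index: int,
    dancer_index: int,
) -> MarkerRecording:
    """One (dancer, stimulus) marker recording with embedded coupling."""
    jmap = default_marker_joint_map()
    n_frames = int(round(spec.duration * spec.sampling_rate))
    if n_frames < 2:
        raise ValueError("duration x rate must give at least 2 frames")
    t = np.arange(n_frames) / spec.sampling_rate

    # stimulus-level structure shared across dancers
    stim_rng = _rng(spec.seed, 23, stimulus_index)
    n_osc = int(stim_rng.integers(3, 9))
    freqs = stim_rng.uniform(0.5, 4.0, size=n_osc)
    shared_phase = stim_rng.uniform(0.0, 2.0 * np.pi, size=(n_osc, 3))

    rng = _rng(spec.seed, 37, dancer_index, stimulus_index)
    is_female = str(dancer_labels["gender"]) == "female"
    scale = 1.0 + 0.06 * spec.gender_effect * (-1.0 if is_female else 1.0)
    coeff = _coupling_coefficients(spec, dancer_labels, jmap)

    markers = list(_SKELETON)
    positions = np.empty((n_frames, len(markers), 3))
    phase_arg = 2.0 * np.pi * freqs[:, None] * t[None, :]  # (n_osc, n_frames)
    for m_idx, m in enumerate(markers):
        rest = scale * np.asarray(_SKELETON[m])
        amp_base = _AMPLITUDE[m] * scale / np.sqrt(n_osc)
        c = coeff[m]
        for ax in range(3):
            amps = amp_base * rng.uniform(0.7, 1.3, size=n_osc)
            jitter = rng.uniform(-np.pi, np.pi, size=n_osc)
            phases = shared_phase[:, ax] + (1.0 - c) * jitter
            wave = (amps[:, None] * np.sin(phase_arg + phases[:, None])).sum(axis=0)
            positions[:, m_idx, ax] = rest[ax] + wave
        positions[:, m_idx, :] += rng.normal(0.0, spec.noise_sd, size=(n_frames, 3))

    return MarkerRecording(
        participant_id=str(dancer_labels.name),
        stimulus_id=f"S{stimulus_index:02d}",
        marker_labels=markers,
        positions=positions,
        sampling_rate=spec.sampling_rate,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Labels, every (dancer, stimulus) recording, and the truth manifest."""
    labels = sample_cohort_labels(spec)
    jmap = default_marker_joint_map()
    recordings = {}
    for d, pid in enumerate(labels.index):
        for s in range(spec.n_stimuli):
            rec = synthesize_recording(labels.loc[pid], spec, s, d)
            recordings[(pid, rec.stimulus_id)] = rec
    joint_to_group = {j: g for g, js in jmap.pair_groups.items() for j in js}
    ground_truth = {
        target: {
            "joints": list(joints),
            "pair_groups": sorted({joint_to_group[j] for j in joints}),
        }
        for target, joints in spec.trait_joint_sets.items()
    }
    return SyntheticCohort(
        spec=spec,
        labels=labels,
        recordings=recordings,
        ground_truth=ground_truth,
        marker_joint_map=jmap,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Emit trajectory TSVs, labels CSV, joint map YAML and truth JSON."""
    from .mocap_io import write_marker_joint_map

    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for (pid, stim), rec in cohort.recordings.items():
        write_marker_recording(rec, rec_dir / f"{pid}__{stim}.tsv")
    cohort.labels.to_csv(outdir / "labels.csv")
    write_marker_joint_map(cohort.marker_joint_map, outdir / "marker_joint_map.yaml")
    spec_dict = asdict(cohort.spec)
    spec_dict["preference_loadings"] = cohort.spec.preference_loadings.tolist()
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({"spec": spec_dict, "targets": cohort.ground_truth}, fh, indent=2)
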