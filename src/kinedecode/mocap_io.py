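"""Reading, writing and basic repair of marker trajectory files.

Trajectory files are wide tab-separated tables: a ``frame`` column, a
``time`` column (seconds), then one ``<marker>_X``/``_Y``/``_Z`` triplet
per marker, in millimetres.  The coordinate convention is right-handed
with the vertical as the third axis.  Missing samples are empty cells.
Two optional comment lines (``# participant_id: ...`` and
``# stimulus_id: ...``) carry identifiers through round trips.

The marker-to-joint mapping is a YAML file listing joint definitions
(joint name -> list of marker names, averaged per frame), the root and
hip joint designations, and the left/right pair groups used for the
12-joint importance reduction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "MarkerRecording",
    "MarkerJointMap",
    "read_marker_recording",
    "write_marker_recording",
    "fill_gaps",
    "trim_to_window",
    "read_marker_joint_map",
    "write_marker_joint_map",
    "default_marker_joint_map",
]


class MocapIOError(ValueError):
    """Raised on malformed trajectory or mapping files."""


@dataclass
class MarkerRecording:
    """Raw per-frame 3-D marker positions for one (participant, stimulus)."""

    participant_id: str
    stimulus_id: str
    marker_labels: list[str]
    positions: np.ndarray  # (frames, markers, 3), millimetres
    sampling_rate: float  # Hz
    missing_mask: np.ndarray = field(default=None)  # (frames, markers) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise MocapIOError(
                f"positions must be (frames, markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise MocapIOError("a recording needs at least 2 frames")
        if len(set(self.marker_labels)) != len(self.marker_labels):
            raise MocapIOError("marker labels must be unique")
        if self.positions.shape[1] != len(self.marker_labels):
            raise MocapIOError(
                f"{len(self.marker_labels)} labels but "
                f"{self.positions.shape[1]} marker columns"
            )
        if not self.sampling_rate > 0:
            raise MocapIOError("sampling_rate must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.positions.shape[:2], dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.positions.shape[:2]:
            raise MocapIOError("missing_mask shape must be (frames, markers)")
        if not np.isfinite(self.positions[~self.missing_mask]).all():
            raise MocapIOError("non-finite positions outside the missing mask")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (frame count / rate)."""
        return self.n_frames / self.sampling_rate


def read_marker_recording(path, expected_rate: float | None = None) -> MarkerRecording:
    """Parse a trajectory TSV file.

    The sampling rate is inferred from the median interval of the time
    column unless ``expected_rate`` is given.
    """
    participant_id, stimulus_id = "", ""
    with open(path) as fh:
        lines = fh.read().splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "participant_id":
                participant_id = value.strip()
            elif key.strip() == "stimulus_id":
                stimulus_id = value.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise MocapIOError(f"{path}: empty file")
    header = body[0].split("\t")
    if header[:2] != ["frame", "time"]:
        raise MocapIOError(f"{path}: header must start with 'frame\\ttime'")
    coord_cols = header[2:]
    if len(coord_cols) == 0 or len(coord_cols) % 3 != 0:
        raise MocapIOError(
            f"{path}: marker column count {len(coord_cols)} is not a multiple of 3"
        )
    marker_labels = []
    for i in range(0, len(coord_cols), 3):
        triplet = coord_cols[i : i + 3]
        stems = [c.rsplit("_", 1) for c in triplet]
        axes = [s[1] if len(s) == 2 else "" for s in stems]
        if axes != ["X", "Y", "Z"] or len({s[0] for s in stems}) != 1:
            raise MocapIOError(f"{path}: malformed marker triplet {triplet}")
        marker_labels.append(stems[0][0])

    n_frames = len(body) - 1
    if n_frames < 2:
        raise MocapIOError(f"{path}: fewer than 2 frames")
    times = np.empty(n_frames)
    flat = np.full((n_frames, len(coord_cols)), np.nan)
    for r, line in enumerate(body[1:]):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise MocapIOError(f"{path}: row {r} has {len(cells)} cells")
        times[r] = float(cells[1])
        for c, cell in enumerate(cells[2:]):
            cell = cell.strip()
            if cell and cell.upper() != "NAN":
                flat[r, c] = float(cell)

    dt = np.diff(times)
    if np.any(dt <= 0):
        raise MocapIOError(f"{path}: time column is not strictly increasing")
    rate = expected_rate if expected_rate is not None else 1.0 / float(np.median(dt))

    positions = flat.reshape(n_frames, len(marker_labels), 3)
    missing = np.isnan(positions).any(axis=2)
    positions = np.where(missing[:, :, None], 0.0, positions)
    return MarkerRecording(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        marker_labels=marker_labels,
        positions=positions,
        sampling_rate=float(rate),
        missing_mask=missing,
    )


def write_marker_recording(rec: MarkerRecording, path) -> None:
    """Write ``rec`` in the dialect :func:`read_marker_recording` accepts."""
    buf = io.StringIO()
    if rec.participant_id:
        buf.write(f"# participant_id: {rec.participant_id}\n")
    if rec.stimulus_id:
        buf.write(f"# stimulus_id: {rec.stimulus_id}\n")
    cols = ["frame", "time"]
    for m in rec.marker_labels:
        cols += [f"{m}_X", f"{m}_Y", f"{m}_Z"]
    buf.write("\t".join(cols) + "\n")
    for f in range(rec.n_frames):
        row = [str(f), repr(f / rec.sampling_rate)]
        for m in range(rec.n_markers):
            if rec.missing_mask[f, m]:
                row += ["", "", ""]
            else:
                row += [repr(float(v)) for v in rec.positions[f, m]]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def fill_gaps(rec: MarkerRecording, max_gap: int) -> MarkerRecording:
    """Fill missing runs of length <= ``max_gap`` by linear interpolation.

    Gaps touching the first or last frame, or longer than ``max_gap``,
    raise :class:`MocapIOError` — those cannot be bridged honestly.
    """
    if not rec.missing_mask.any():
        return rec
    positions = rec.positions.copy()
    frames = np.arange(rec.n_frames)
    for m in range(rec.n_markers):
        miss = rec.missing_mask[:, m]
        if not miss.any():
            continue
        if miss[0] or miss[-1]:
            raise MocapIOError(
                f"marker {rec.marker_labels[m]!r}: gap at sequence boundary"
            )
        # contiguous runs of missing frames
        starts = np.flatnonzero(miss & ~np.roll(miss, 1))
        ends = np.flatnonzero(miss & ~np.roll(miss, -1))
        for s, e in zip(starts, ends):
            if e - s + 1 > max_gap:
                raise MocapIOError(
                    f"marker {rec.marker_labels[m]!r}: gap of {e - s + 1} frames "
                    f"exceeds max_gap={max_gap}"
                )
        good = ~miss
        for ax in range(3):
            positions[miss, m, ax] = np.interp(
                frames[miss], frames[good], rec.positions[good, m, ax]
            )
    return replace(
        rec,
        positions=positions,
        missing_mask=np.zeros_like(rec.missing_mask),
    )


def trim_to_window(rec: MarkerRecording, start: float, end: float) -> MarkerRecording:
    """Keep frames with time in ``[start, end)`` seconds."""
    if not 0 <= start < end:
        raise MocapIOError(f"invalid window [{start}, {end})")
    i0 = int(round(start * rec.sampling_rate))
    i1 = int(round(end * rec.sampling_rate))
    if i1 > rec.n_frames:
        raise MocapIOError(
            f"window end {end} s exceeds recording duration {rec.duration} s"
        )
    if i1 - i0 < 2:
        raise MocapIOError("trim window shorter than 2 frames")
    return replace(
        rec,
        positions=rec.positions[i0:i1],
        missing_mask=rec.missing_mask[i0:i1],
    )


@dataclass
class MarkerJointMap:
    """Marker-to-joint reduction plus the pair groups for the 12-joint view."""

    joint_definitions: dict[str, list[str]]  # ordered joint -> markers
    root_joint: str
    left_hip_joint: str
    right_hip_joint: str
    pair_groups: dict[str, list[str]]  # ordered group -> 1 or 2 joints

    def __post_init__(self) -> None:
        joints = list(self.joint_definitions)
        for role, name in (
            ("root", self.root_joint),
            ("left hip", self.left_hip_joint),
            ("right hip", self.right_hip_joint),
        ):
            if name not in self.joint_definitions:
                raise MocapIOError(f"{role} joint {name!r} is not a defined joint")
        for joint, markers in self.joint_definitions.items():
            if not markers:
                raise MocapIOError(f"joint {joint!r} has an empty marker list")
        seen: dict[str, str] = {}
        for group, members in self.pair_groups.items():
            if not 1 <= len(members) <= 2:
                raise MocapIOError(f"pair group {group!r} must have 1 or 2 joints")
            for j in members:
                if j not in self.joint_definitions:
                    raise MocapIOError(f"pair group {group!r} references unknown joint {j!r}")
                if j in seen:
                    raise MocapIOError(
                        f"joint {j!r} appears in pair groups {seen[j]!r} and {group!r}"
                    )
                seen[j] = group
        if set(seen) != set(joints):
            missing = set(joints) - set(seen)
            raise MocapIOError(f"joints not covered by any pair group: {sorted(missing)}")

    @property
    def joint_labels(self) -> list[str]:
        return list(self.joint_definitions)

    @property
    def n_joints(self) -> int:
        return len(self.joint_definitions)

    @property
    def group_labels(self) -> list[str]:
        return list(self.pair_groups)


def read_marker_joint_map(path) -> MarkerJointMap:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return MarkerJointMap(
            joint_definitions={j: list(m) for j, m in raw["joints"].items()},
            root_joint=raw["root_joint"],
            left_hip_joint=raw["left_hip_joint"],
            right_hip_joint=raw["right_hip_joint"],
            pair_groups={g: list(m) for g, m in raw["pair_groups"].items()},
        )
    except KeyError as exc:
        raise MocapIOError(f"{path}: missing required key {exc}") from exc


def write_marker_joint_map(jmap: MarkerJointMap, path) -> None:
    payload = {
        "joints": {j: list(m) for j, m in jmap.joint_definitions.items()},
        "root_joint": jmap.root_joint,
        "left_hip_joint": jmap.left_hip_joint,
        "right_hip_joint": jmap.right_hip_joint,
        "pair_groups": {g: list(m) for g, m in jmap.pair_groups.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def default_marker_joint_map() -> MarkerJointMap:
    """The default 20-joint, 12-group reduction of a 21-marker layout.

    Root is the mean of the two back-hip markers; the neck is the mean of
    the shoulder markers; the torso the mean of shoulders and hips; the
    head the mean of three head markers.  All remaining joints pass a
    single marker through.
    """
    side = lambda base: {f"{s}_{base}": [f"{base}_{s}"] for s in ("left", "right")}
    joints: dict[str, list[str]] = {
        "root": ["hip_back_left", "hip_back_right"],
        "left_hip": ["hip_left"],
        "right_hip": ["hip_right"],
        "torso": ["shoulder_left", "shoulder_right", "hip_left", "hip_right"],
        "neck": ["shoulder_left", "shoulder_right"],
        "head": ["head_front", "head_left", "head_right"],
        **side("shoulder"),
        **side("elbow"),
        **side("wrist"),
        **side("finger"),
        **side("knee"),
        **side("ankle"),
        **side("toe"),
    }
    pair_groups: dict[str, list[str]] = {
        "root": ["root"],
        "hips": ["left_hip", "right_hip"],
        "torso": ["torso"],
        "neck": ["neck"],
        "head": ["head"],
        "shoulder": ["left_shoulder", "right_shoulder"],
        "elbow": ["left_elbow", "right_elbow"],
        "wrist": ["left_wrist", "right_wrist"],
        "finger": ["left_finger", "right_finger"],
        "knee": ["left_knee", "right_knee"],
        "ankle": ["left_ankle", "right_ankle"],
        "toe": ["left_toe", "right_toe"],
    }
    return MarkerJointMap(
        joint_definitions=joints,
        root_joint="root",
        left_hip_joint="left_hip",
        right_hip_joint="right_hip",
        pair_groups=pair_groups,
    )
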