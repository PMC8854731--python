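"""Joint derivation, body-local coordinates, and velocity estimation.

Axis convention: index 0 = mediolateral (left-right), index 1 =
anteroposterior (back-front), index 2 = vertical.  In the local frame
the root joint sits at the origin each frame and the left-hip to
right-hip line is rotated onto the mediolateral axis about the
vertical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .mocap_io import MarkerJointMap, MarkerRecording

__all__ = [
    "JointRecording",
    "derive_joints",
    "to_local_coordinates",
    "velocity_butterworth",
    "velocity_savgol",
]

AXIS_NAMES = ("mediolateral", "anteroposterior", "vertical")


@dataclass
class JointRecording:
    """Per-frame joint trajectories (position or velocity)."""

    joint_labels: list[str]
    values: np.ndarray  # (frames, joints, 3); mm or mm/s
    sampling_rate: float
    frame_kind: str = "position"  # position | velocity
    coordinate_frame: str = "global"  # global | local
    participant_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"values must be (frames, joints, 3), got {self.values.shape}")
        if self.values.shape[1] != len(self.joint_labels):
            raise ValueError("joint count does not match labels")
        if self.frame_kind not in ("position", "velocity"):
            raise ValueError(f"bad frame_kind {self.frame_kind!r}")
        if self.coordinate_frame not in ("global", "local"):
            raise ValueError(f"bad coordinate_frame {self.coordinate_frame!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite joint values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_joints(self) -> int:
        return self.values.shape[1]


def derive_joints(rec: MarkerRecording, jmap: MarkerJointMap) -> JointRecording:
    """Average mapped markers into joints, in map order.

    Requires a gap-free recording: run :func:`~kinedecode.mocap_io.fill_gaps`
    first if the capture has occlusions.
    """
    if rec.missing_mask.any():
        raise ValueError("recording has missing samples; fill gaps first")
    index = {m: i for i, m in enumerate(rec.marker_labels)}
    out = np.empty((rec.n_frames, jmap.n_joints, 3))
    for j, (joint, markers) in enumerate(jmap.joint_definitions.items()):
        try:
            cols = [index[m] for m in markers]
        except KeyError as exc:
            raise ValueError(f"joint {joint!r} references unknown marker {exc}") from exc
        out[:, j, :] = rec.positions[:, cols, :].mean(axis=1)
    return JointRecording(
        joint_labels=jmap.joint_labels,
        values=out,
        sampling_rate=rec.sampling_rate,
        frame_kind="position",
        coordinate_frame="global",
        participant_id=rec.participant_id,
        stimulus_id=rec.stimulus_id,
    )


def to_local_coordinates(
    jrec: JointRecording,
    jmap: MarkerJointMap,
    rotation_mode: str = "per_frame",
) -> JointRecording:
    """Express positions relative to the root, hips aligned mediolaterally.

    Each frame is translated so the root joint is the origin, then rotated
    about the vertical axis so the left-hip -> right-hip vector points along
    the positive mediolateral axis.  ``rotation_mode`` chooses between a
    fresh rotation per frame (default) and the first frame's rotation
    applied throughout.
    """
    if jrec.frame_kind != "position":
        raise ValueError("local transform operates on position data")
    if rotation_mode not in ("per_frame", "first_frame"):
        raise ValueError(f"bad rotation_mode {rotation_mode!r}")
    labels = jrec.joint_labels
    r = labels.index(jmap.root_joint)
    lh = labels.index(jmap.left_hip_joint)
    rh = labels.index(jmap.right_hip_joint)

    centred = jrec.values - jrec.values[:, r : r + 1, :]
    hip = centred[:, rh, :] - centred[:, lh, :]  # left -> right
    norm = np.hypot(hip[:, 0], hip[:, 1])
    if np.any(norm < 1e-9):
        raise ValueError("hip joints coincide in the horizontal plane; rotation undefined")
    cos = hip[:, 0] / norm
    sin = hip[:, 1] / norm
    if rotation_mode == "first_frame":
        cos = np.full_like(cos, cos[0])
        sin = np.full_like(sin, sin[0])
    # rotate by -theta about the vertical axis, frame-wise
    x, y = centred[..., 0], centred[..., 1]
    out = np.empty_like(centred)
    out[..., 0] = cos[:, None] * x + sin[:, None] * y
    out[..., 1] = -sin[:, None] * x + cos[:, None] * y
    out[..., 2] = centred[..., 2]
    return replace(jrec, values=out, coordinate_frame="local")


def _differentiate(values: np.ndarray, rate: float) -> np.ndarray:
    # central differences interior, one-sided at the ends
    return np.gradient(values, axis=0) * rate


def velocity_butterworth(
    jrec: JointRecording, cutoff: float = 24.0, order: int = 2
) -> JointRecording:
    """Velocity by time differentiation then zero-phase Butterworth low-pass."""
    if jrec.frame_kind != "position":
        raise ValueError("velocity estimation needs position input")
    nyquist = jrec.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    vel = _differentiate(jrec.values, jrec.sampling_rate)
    sos = signal.butter(order, cutoff, btype="low", fs=jrec.sampling_rate, output="sos")
    pad = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default padlen
    if jrec.n_frames <= pad:
        raise ValueError(f"need more than {pad} frames for the filter warm-up")
    smoothed = signal.sosfiltfilt(sos, vel, axis=0)
    return replace(jrec, values=smoothed, frame_kind="velocity")


def velocity_savgol(
    jrec: JointRecording, window: int = 7, polyorder: int = 2
) -> JointRecording:
    """Velocity as the Savitzky-Golay first derivative (FIR smoothing)."""
    if jrec.frame_kind != "position":
        raise ValueError("velocity estimation needs position input")
    if window % 2 == 0 or window < polyorder + 1:
        raise ValueError(f"window must be odd and > polyorder, got {window}")
    if jrec.n_frames < window:
        raise ValueError(f"need at least {window} frames")
    vel = signal.savgol_filter(
        jrec.values,
        window_length=window,
        polyorder=polyorder,
        deriv=1,
        delta=1.0 / jrec.sampling_rate,
        axis=0,
        mode="interp",
    )
    return replace(jrec, values=vel, frame_kind="velocity")
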