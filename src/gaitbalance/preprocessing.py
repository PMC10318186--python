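"""Input normalization for the classifier.

Pipeline (in order): simplify the 32-joint skeleton to 21 joints, keep the
last 20 frames, translate all coordinates so the pelvis of the first retained
frame sits at the origin, then select the requested joint group.  Re-centering
happens on the full simplified skeleton, before group selection, so groups
that lack the pelvis (e.g. legs-only) are still expressed in pelvis-anchored
coordinates.

The tail window is used (rather than the head) because subjects sometimes
stand still for a few frames after the walk command; the last 20 frames are
reliably walking.  Centering on the first *retained* frame gives the analyzed
window a canonical origin regardless of where on the walkway it started.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import SkeletonSequence, FULL32, SIMPLIFIED21
from .skeleton import (
    Joint,
    JointGroup,
    N_JOINTS_FULL,
    N_JOINTS_SIMPLIFIED,
    SIMPLIFIED_JOINTS,
    joint_group,
)

DEFAULT_WINDOW = 20


@dataclass
class PreprocessedSample:
    """A fixed-size classifier input: ``(window, J, 3)`` tensor plus label.

    The tensor is pelvis-centered and in meters; ``group`` names the joint
    subset it contains (columns in ascending full-skeleton joint index).
    """

    tensor: np.ndarray
    label: int
    subject_id: int
    trial_id: int
    group: str

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3 or self.tensor.shape[2] != 3:
            raise ValueError(f"tensor must be (window, J, 3), got {self.tensor.shape}")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("tensor contains non-finite values")

    @property
    def n_scalars(self) -> int:
        return int(np.prod(self.tensor.shape))


def simplify_joints(seq: SkeletonSequence) -> SkeletonSequence:
    """Reduce a 32-joint sequence to the simplified 21-joint skeleton.

    Idempotent: a sequence already on the simplified skeleton is returned
    unchanged (a copy).
    """
    if seq.joint_set == SIMPLIFIED21:
        return replace(seq, frames=seq.frames.copy())
    if seq.n_joints != N_JOINTS_FULL:
        raise ValueError(f"expected 32 joints, got {seq.n_joints}")
    return replace(seq, frames=seq.frames[:, list(SIMPLIFIED_JOINTS), :].copy(),
                   joint_set=SIMPLIFIED21)


def trim_to_window(seq: SkeletonSequence, window: int = DEFAULT_WINDOW) -> SkeletonSequence:
    """Keep the last ``window`` frames, preserving temporal order."""
    if seq.n_frames < window:
        raise ValueError(
            f"sequence has {seq.n_frames} frames, fewer than window={window}"
        )
    return replace(seq, frames=seq.frames[seq.n_frames - window:].copy())


def recenter_to_pelvis(seq: SkeletonSequence) -> SkeletonSequence:
    """Subtract the first frame's pelvis position from every coordinate.

    The pelvis is joint 0 in both the full and the simplified skeleton
    (simplification preserves ascending index order and retains the pelvis).
    """
    origin = seq.frames[0, int(Joint.PELVIS), :].copy()
    return replace(seq, frames=seq.frames - origin[None, None, :])


def select_joints(seq: SkeletonSequence, group: JointGroup | str) -> np.ndarray:
    """Select a joint group's columns; returns a ``(T, |group|, 3)`` array.

    The group's indices are in the full 32-joint numbering; on a simplified
    sequence they are mapped through the simplified ordering.
    """
    if isinstance(group, str):
        group = joint_group(group)
    if seq.joint_set == SIMPLIFIED21:
        lookup = {j: k for k, j in enumerate(SIMPLIFIED_JOINTS)}
    else:
        lookup = {j: j for j in range(N_JOINTS_FULL)}
    missing = [j for j in group.indices if j not in lookup]
    if missing:
        raise ValueError(
            f"group {group.name} requests joints absent from the sequence: {missing}"
        )
    cols = [lookup[j] for j in group.indices]
    return seq.frames[:, cols, :].copy()


def preprocess(
    seq: SkeletonSequence,
    group: JointGroup | str = "A0",
    window: int = DEFAULT_WINDOW,
) -> PreprocessedSample:
    """Full normalization: simplify -> trim -> recenter -> select.

    For the default A0 group the result is 20 x 21 x 3 = 1,260 scalars.
    """
    if isinstance(group, str):
        group = joint_group(group)
    s = simplify_joints(seq) if seq.joint_set == FULL32 else seq
    s = trim_to_window(s, window)
    s = recenter_to_pelvis(s)
    tensor = select_joints(s, group)
    return PreprocessedSample(
        tensor=tensor,
        label=seq.level,
        subject_id=seq.subject_id,
        trial_id=seq.trial_id,
        group=group.name,
    )


def preprocess_dataset(dataset, group="A0", window: int = DEFAULT_WINDOW):
    """Preprocess every sequence in a dataset; returns a list of samples."""
    return [preprocess(seq, group, window) for seq in dataset]


def save_samples(samples: list[PreprocessedSample], path) -> None:
    """Store preprocessed samples in an ``.npz`` container (tensor stack,
    labels, subject/trial ids, group name)."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    X, y, subjects = samples_to_arrays(samples)
    trials = np.array([s.trial_id for s in samples], dtype=np.int64)
    groups = {s.group for s in samples}
    if len(groups) != 1:
        raise ValueError(f"samples mix joint groups: {groups}")
    np.savez(path, X=X, y=y, subjects=subjects, trials=trials,
             group=np.array(groups.pop()))


def load_samples(path) -> list[PreprocessedSample]:
    """Load samples stored by :func:`save_samples`."""
    with np.load(path, allow_pickle=False) as data:
        group = str(data["group"])
        return [
            PreprocessedSample(
                tensor=data["X"][i], label=int(data["y"][i]),
                subject_id=int(data["subjects"][i]),
                trial_id=int(data["trials"][i]), group=group,
            )
            for i in range(len(data["y"]))
        ]


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into ``(X, y, subjects)`` arrays.

    ``X`` has shape ``(n, window, J, 3)``; ``y`` and ``subjects`` are int
    vectors.
    """
    X = np.stack([s.tensor for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    subjects = np.array([s.subject_id for s in samples], dtype=np.int64)
    return X, y, subjects
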