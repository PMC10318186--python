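"""Containers and on-disk format for skeleton walking sequences.

A dataset is a flat collection of walking trials.  On disk it is JSON Lines:
the first line is a metadata record (``{"meta": {...}}``) holding provenance
(generator configuration, seed, free text), and every following line is one
sequence::

    {"subject_id": 0, "trial_id": 3, "level": 1, "joint_set": "FULL32",
     "frames": [[[x, y, z], ... J joints], ... T frames]}

Coordinates are meters.  A CSV exporter (one row per joint per frame) is
provided for interoperability with spreadsheet / R workflows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .skeleton import N_JOINTS_FULL, N_JOINTS_SIMPLIFIED

logger = logging.getLogger(__name__)

FULL32 = "FULL32"
SIMPLIFIED21 = "SIMPLIFIED21"

_JOINT_COUNTS = {FULL32: N_JOINTS_FULL, SIMPLIFIED21: N_JOINTS_SIMPLIFIED}

LEVELS = (0, 1, 2)


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset record violates the schema."""


@dataclass
class SkeletonSequence:
    """One recorded or simulated walk.

    Attributes
    ----------
    subject_id, trial_id : int
        Identity of the walker and the repetition index.
    level : int
        Balance-impairment level: 0 none, 1 moderate, 2 severe.
    frames : numpy.ndarray
        Shape ``(T, J, 3)`` float64, meters.  Axes: x walking direction,
        y left-right, z up-down.
    joint_set : str
        ``"FULL32"`` or ``"SIMPLIFIED21"``.
    """

    subject_id: int
    trial_id: int
    level: int
    frames: np.ndarray
    joint_set: str = FULL32

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level}")
        if self.joint_set not in _JOINT_COUNTS:
            raise ValueError(f"joint_set must be FULL32 or SIMPLIFIED21")
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (T, J, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if self.frames.shape[1] != _JOINT_COUNTS[self.joint_set]:
            raise ValueError(
                f"{self.joint_set} sequence must have "
                f"{_JOINT_COUNTS[self.joint_set]} joints, got {self.frames.shape[1]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_joints(self) -> int:
        return self.frames.shape[1]

    def key(self) -> tuple[int, int, int]:
        return (self.subject_id, self.trial_id, self.level)


@dataclass
class Dataset:
    """A collection of :class:`SkeletonSequence` with provenance metadata."""

    samples: list[SkeletonSequence] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [s.key() for s in self.samples]
        if len(set(keys)) != len(keys):
            seen: set[tuple[int, int, int]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(
                        f"duplicate (subject_id, trial_id, level) triple: {k}"
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SkeletonSequence]:
        return iter(self.samples)

    @property
    def subjects(self) -> list[int]:
        return sorted({s.subject_id for s in self.samples})


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as JSON Lines (meta record first)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(json.dumps({"meta": dataset.provenance}) + "\n")
        for s in dataset.samples:
            rec = {
                "subject_id": int(s.subject_id),
                "trial_id": int(s.trial_id),
                "level": int(s.level),
                "joint_set": s.joint_set,
                "frames": s.frames.tolist(),
            }
            fh.write(json.dumps(rec) + "\n")


def load_dataset(path: str | Path) -> Dataset:
    """Read a JSON Lines dataset written by :func:`save_dataset`.

    Raises
    ------
    DatasetFormatError
        On a malformed record, inconsistent joint count, or an out-of-range
        balance level; the message names the offending line.
    """
    path = Path(path)
    samples: list[SkeletonSequence] = []
    provenance: dict = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DatasetFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if "meta" in rec:
                provenance = rec["meta"]
                continue
            try:
                seq = SkeletonSequence(
                    subject_id=int(rec["subject_id"]),
                    trial_id=int(rec["trial_id"]),
                    level=int(rec["level"]),
                    frames=np.asarray(rec["frames"], dtype=np.float64),
                    joint_set=rec.get("joint_set", FULL32),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise DatasetFormatError(f"{path}:{lineno}: bad record: {exc}") from exc
            samples.append(seq)
    if not samples:
        logger.warning("loaded empty dataset from %s", path)
    return Dataset(samples=samples, provenance=provenance)


def export_csv(dataset: Dataset, path: str | Path) -> None:
    """Export one row per (sequence, frame, joint) as CSV."""
    import csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "trial_id", "level", "frame", "joint", "x", "y", "z"])
        for s in dataset.samples:
            for t in range(s.n_frames):
                for j in range(s.n_joints):
                    x, y, z = s.frames[t, j]
                    w.writerow([s.subject_id, s.trial_id, s.level, t, j,
                                repr(x), repr(y), repr(z)])
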