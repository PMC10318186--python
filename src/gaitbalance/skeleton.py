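"""Skeleton model: the Kinect body-tracking joint hierarchy and named joint groups.

The Azure Kinect body tracker reports 32 joints per frame, indexed from the
pelvis outward.  For balance assessment the distal hand joints and the face
joints carry little information, so analyses run on a simplified 21-joint
skeleton, and the ablation study further restricts the input to named
sub-groups of those 21 joints (trunk-only, legs-only, arms removed, ...).

Axis convention used throughout the package: x = walking (front-back)
direction, y = left-right, z = up-down.  Coordinates are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum


class Joint(IntEnum):
    """The 32-joint Azure Kinect body-tracking hierarchy, in sensor order."""

    PELVIS = 0
    SPINE_NAVEL = 1
    SPINE_CHEST = 2
    NECK = 3
    CLAVICLE_LEFT = 4
    SHOULDER_LEFT = 5
    ELBOW_LEFT = 6
    WRIST_LEFT = 7
    HAND_LEFT = 8
    HANDTIP_LEFT = 9
    THUMB_LEFT = 10
    CLAVICLE_RIGHT = 11
    SHOULDER_RIGHT = 12
    ELBOW_RIGHT = 13
    WRIST_RIGHT = 14
    HAND_RIGHT = 15
    HANDTIP_RIGHT = 16
    THUMB_RIGHT = 17
    HIP_LEFT = 18
    KNEE_LEFT = 19
    ANKLE_LEFT = 20
    FOOT_LEFT = 21
    HIP_RIGHT = 22
    KNEE_RIGHT = 23
    ANKLE_RIGHT = 24
    FOOT_RIGHT = 25
    HEAD = 26
    NOSE = 27
    EYE_LEFT = 28
    EAR_LEFT = 29
    EYE_RIGHT = 30
    EAR_RIGHT = 31


N_JOINTS_FULL = 32
N_JOINTS_SIMPLIFIED = 21

#: Joints retained by the simplified 21-joint skeleton: hands, hand tips,
#: thumbs, nose, eyes and ears are dropped.
SIMPLIFIED_JOINTS: tuple[int, ...] = (
    0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14,
    18, 19, 20, 21, 22, 23, 24, 25, 26,
)


@dataclass(frozen=True)
class JointGroup:
    """A named subset of the simplified skeleton used as classifier input.

    ``indices`` are joint indices in the FULL 32-joint numbering, sorted
    ascending.  All groups are subsets of the simplified 21-joint set.
    """

    name: str
    description: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(self.indices)))

    def __len__(self) -> int:
        return len(self.indices)


def _without(base: tuple[int, ...], removed: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(i for i in base if i not in removed)


_A0 = SIMPLIFIED_JOINTS

JOINT_GROUPS: dict[str, JointGroup] = {
    g.name: g
    for g in (
        JointGroup("A0", "all simplified joints (control)", _A0),
        JointGroup("T1", "except head", _without(_A0, (Joint.HEAD,))),
        JointGroup("T2", "except head, neck", _without(_A0, (Joint.HEAD, Joint.NECK))),
        JointGroup("H1", "except wrists",
                   _without(_A0, (Joint.WRIST_LEFT, Joint.WRIST_RIGHT))),
        JointGroup("H2", "except wrists, elbows",
                   _without(_A0, (Joint.WRIST_LEFT, Joint.WRIST_RIGHT,
                                  Joint.ELBOW_LEFT, Joint.ELBOW_RIGHT))),
        JointGroup("H3", "except wrists, elbows, shoulders",
                   _without(_A0, (Joint.WRIST_LEFT, Joint.WRIST_RIGHT,
                                  Joint.ELBOW_LEFT, Joint.ELBOW_RIGHT,
                                  Joint.SHOULDER_LEFT, Joint.SHOULDER_RIGHT))),
        JointGroup("H4", "except wrists, elbows, shoulders, clavicles",
                   _without(_A0, (Joint.WRIST_LEFT, Joint.WRIST_RIGHT,
                                  Joint.ELBOW_LEFT, Joint.ELBOW_RIGHT,
                                  Joint.SHOULDER_LEFT, Joint.SHOULDER_RIGHT,
                                  Joint.CLAVICLE_LEFT, Joint.CLAVICLE_RIGHT))),
        JointGroup("L1", "except feet",
                   _without(_A0, (Joint.FOOT_LEFT, Joint.FOOT_RIGHT))),
        JointGroup("L2", "except feet, ankles",
                   _without(_A0, (Joint.FOOT_LEFT, Joint.FOOT_RIGHT,
                                  Joint.ANKLE_LEFT, Joint.ANKLE_RIGHT))),
        JointGroup("L3", "except feet, ankles, knees",
                   _without(_A0, (Joint.FOOT_LEFT, Joint.FOOT_RIGHT,
                                  Joint.ANKLE_LEFT, Joint.ANKLE_RIGHT,
                                  Joint.KNEE_LEFT, Joint.KNEE_RIGHT))),
        JointGroup("L4", "except feet, ankles, knees, hips",
                   _without(_A0, (Joint.FOOT_LEFT, Joint.FOOT_RIGHT,
                                  Joint.ANKLE_LEFT, Joint.ANKLE_RIGHT,
                                  Joint.KNEE_LEFT, Joint.KNEE_RIGHT,
                                  Joint.HIP_LEFT, Joint.HIP_RIGHT))),
        JointGroup("G1", "only pelvis, spine navel, spine chest",
                   (Joint.PELVIS, Joint.SPINE_NAVEL, Joint.SPINE_CHEST)),
        JointGroup("G2", "only feet, ankles, knees, hips",
                   (Joint.HIP_LEFT, Joint.KNEE_LEFT, Joint.ANKLE_LEFT,
                    Joint.FOOT_LEFT, Joint.HIP_RIGHT, Joint.KNEE_RIGHT,
                    Joint.ANKLE_RIGHT, Joint.FOOT_RIGHT)),
    )
}


def joint_group(name: str) -> JointGroup:
    """Look up a joint group by name (case-insensitive).

    Parameters
    ----------
    name
        One of ``A0, T1, T2, H1, H2, H3, H4, L1, L2, L3, L4, G1, G2``.

    Raises
    ------
    KeyError
        If the name is not a defined group.
    """
    key = name.upper()
    if key not in JOINT_GROUPS:
        raise KeyError(
            f"unknown joint group {name!r}; valid names: "
            + ", ".join(sorted(JOINT_GROUPS))
        )
    return JOINT_GROUPS[key]


def _check_group_tables() -> None:
    # The derived groups must match the published index lists exactly; any
    # drift here would silently change every downstream experiment.
    expected = {
        "A0": (0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14,
               18, 19, 20, 21, 22, 23, 24, 25, 26),
        "T1": (0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14,
               18, 19, 20, 21, 22, 23, 24, 25),
        "T2": (0, 1, 2, 4, 5, 6, 7, 11, 12, 13, 14,
               18, 19, 20, 21, 22, 23, 24, 25),
        "H1": (0, 1, 2, 3, 4, 5, 6, 11, 12, 13,
               18, 19, 20, 21, 22, 23, 24, 25, 26),
        "H2": (0, 1, 2, 3, 4, 5, 11, 12, 18, 19, 20, 21, 22, 23, 24, 25, 26),
        "H3": (0, 1, 2, 3, 4, 11, 18, 19, 20, 21, 22, 23, 24, 25, 26),
        "H4": (0, 1, 2, 3, 18, 19, 20, 21, 22, 23, 24, 25, 26),
        "L1": (0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14,
               18, 19, 20, 22, 23, 24, 26),
        "L2": (0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14, 18, 19, 22, 23, 26),
        "L3": (0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14, 18, 22, 26),
        "L4": (0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14, 26),
        "G1": (0, 1, 2),
        "G2": (18, 19, 20, 21, 22, 23, 24, 25),
    }
    a0 = set(JOINT_GROUPS["A0"].indices)
    for name, idx in expected.items():
        got = JOINT_GROUPS[name].indices
        if got != idx:
            raise AssertionError(f"joint group {name} mismatch: {got} != {idx}")
        if not set(idx) <= a0:
            raise AssertionError(f"joint group {name} not a subset of A0")


_check_group_tables()
del _check_group_tables
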