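"""Joint and task repertoire of the upper-limb movement protocol.

The kinematic model exposes five joints with twelve angle components
(degrees of freedom): trunk (3), scapula (3), shoulder (3), elbow (2)
and wrist (1).  Eight reach / reach-to-grasp / hand-to-body tasks are
analysed, each time-normalized to a 0-100% movement cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: canonical component order per joint (vector dimension p = len(components))
JOINTS: dict[str, tuple[str, ...]] = {
    "trunk": ("rotation", "lateral_flexion", "flexion_extension"),
    "scapula": ("tilting", "pro_retraction", "rotation"),
    "shoulder": ("rotation", "elevation_plane", "elevation"),
    "elbow": ("flexion_extension", "pro_supination"),
    "wrist": ("flexion_extension",),
}

#: the eight default tasks: reach forward/upward/sideways, reach-to-grasp
#: sphere/vertical cylinder, hand to head/mouth/contralateral shoulder
TASKS: tuple[str, ...] = ("RF", "RU", "RS", "RGS", "RGV", "HTH", "HTM", "HTS")

#: all twelve (joint, component) channels in canonical order
CHANNELS: tuple[tuple[str, str], ...] = tuple(
    (joint, comp) for joint, comps in JOINTS.items() for comp in comps
)


@dataclass(frozen=True)
class JointSpec:
    """One joint and its ordered angle components."""

    joint: str
    components: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        comps = self.components or JOINTS.get(self.joint, ())
        if not comps:
            raise ValueError(f"unknown joint {self.joint!r} and no components given")
        object.__setattr__(self, "components", tuple(comps))

    @property
    def p(self) -> int:
        """Vector dimension (number of angle components)."""
        return len(self.components)


def joint_spec(joint: str) -> JointSpec:
    """Return the canonical :class:`JointSpec` for a named joint."""
    if joint not in JOINTS:
        raise KeyError(f"unknown joint {joint!r}; expected one of {sorted(JOINTS)}")
    return JointSpec(joint, JOINTS[joint])


def channel_index(channels: tuple[tuple[str, str], ...], joint: str, component: str) -> int:
    try:
        return channels.index((joint, component))
    except ValueError:
        raise KeyError(f"channel ({joint!r}, {component!r}) not present") from None
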