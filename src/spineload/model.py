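"""Simplified rigid-body trunk model.

The spine chain comprises seven rigid bodies — pelvis, five lumbar vertebrae
(L5..L1) and one rigid thoracic segment — linked by six 3-DoF spherical
joints (L5-S1 caudally up to T12-L1).  Head and arms are massed appendages of
the thorax: the arm segment centres of mass sit on the shoulder-to-hand line
so that hand targets determine arm gravity levers without an arm-joint model.

Muscle fascicles are straight lines between an origin on the pelvis and an
insertion on a lumbar vertebra (local group) or the thorax (global group);
a fascicle loads every joint between its two attachment segments.  The
intra-abdominal pressure (IAP) is modelled as an upward force of magnitude
``pressure x effective area`` acting at a point anterior to the T12-L1 joint,
which yields an extension moment at every lumbar level; the pressure is
bounded above by 26.6 kPa.

Conventions: right-handed world frame, X anterior, Y to the subject's left,
Z superior; angles in degrees at interfaces; positive flexion about +Y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .anthropometry import ParameterSet, SubjectProfile, muscle_strength, segment_masses
from .config import load_config
from .kinematics import Posture, euler_to_matrix

SEGMENT_ORDER = ("pelvis", "L5", "L4", "L3", "L2", "L1", "thorax")
# joint j connects SEGMENT_ORDER[j] (inferior) and SEGMENT_ORDER[j+1] (superior)
JOINT_ORDER = ("L5S1", "L4L5", "L3L4", "L2L3", "L1L2", "T12L1")


@dataclass(frozen=True)
class Segment:
    name: str
    mass: float
    length: float
    com_offset: np.ndarray  # in the segment's own frame, origin = proximal joint

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name} must have positive length")
        if self.mass < 0:
            raise ValueError(f"segment {self.name} mass must be non-negative")
        object.__setattr__(self, "com_offset", np.asarray(self.com_offset, dtype=float))


@dataclass(frozen=True)
class MuscleFascicle:
    """A muscle line of action: >= 2 path points anchored to segments,
    ordered caudal to cranial (origin on the pelvis first, insertion last).

    Via points on intermediate vertebrae let long extensors follow the spinal
    curvature instead of bow-stringing across flexed joints.  For a
    frictionless via-point path the moment about a joint — and the net force
    the fascicle exerts on the free body above the joint — depend only on the
    path segment crossing that joint; the bending forces at via points on
    superior segments cancel pairwise.
    """

    name: str
    muscle: str
    group: str  # "global" or "local"
    side: str   # "left" or "right"
    pcsa: float
    strength: float
    path: tuple[tuple[str, np.ndarray], ...]  # (segment, xyz in segment frame)

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError(f"fascicle {self.name} must have positive strength")
        if len(self.path) < 2:
            raise ValueError(f"fascicle {self.name} needs at least two path points")
        path = tuple(
            (seg, np.asarray(xyz, dtype=float)) for seg, xyz in self.path
        )
        indices = [SEGMENT_ORDER.index(seg) for seg, _ in path]
        if indices != sorted(indices):
            raise ValueError(
                f"fascicle {self.name} path must run caudal to cranial"
            )
        if indices[0] == indices[-1]:
            raise ValueError(f"fascicle {self.name} must span two different segments")
        object.__setattr__(self, "path", path)

    @property
    def origin_segment(self) -> str:
        return self.path[0][0]

    @property
    def insertion_segment(self) -> str:
        return self.path[-1][0]

    @property
    def inferior_index(self) -> int:
        return SEGMENT_ORDER.index(self.origin_segment)

    @property
    def superior_index(self) -> int:
        return SEGMENT_ORDER.index(self.insertion_segment)

    def crosses_joint(self, joint_index: int) -> bool:
        return self.inferior_index <= joint_index < self.superior_index

    def crossing_pair(self, joint_index: int) -> tuple[int, int]:
        """Indices of the path points straddling a joint (below, above)."""
        if not self.crosses_joint(joint_index):
            raise ValueError(f"{self.name} does not cross joint {joint_index}")
        below = max(
            i
            for i, (seg, _) in enumerate(self.path)
            if SEGMENT_ORDER.index(seg) <= joint_index
        )
        return below, below + 1


@dataclass(frozen=True)
class HandLoad:
    """External load carried in the hands (box, dumbbells, or one-handed)."""

    mass: float
    attachment: str  # bilateral_box | bilateral_dumbbells | unilateral
    positions: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("hand load mass must be non-negative")
        if self.attachment not in ("bilateral_box", "bilateral_dumbbells", "unilateral"):
            raise ValueError(f"unknown attachment {self.attachment!r}")
        if self.attachment == "unilateral" and len(self.positions) > 1:
            raise ValueError("a unilateral load has exactly one position")

    def point_masses(self) -> list[tuple[float, np.ndarray]]:
        """Split the total mass over the contact positions (50/50 bilaterally)."""
        if self.mass == 0 or not self.positions:
            return []
        share = self.mass / len(self.positions)
        return [(share, np.asarray(p, dtype=float)) for p in self.positions]


@dataclass(frozen=True)
class IAPConfig:
    max_pressure_kpa: float = 26.6
    effective_area_m2: float = 0.010
    lever_arm_m: float = 0.050

    def __post_init__(self) -> None:
        if self.max_pressure_kpa < 0 or self.effective_area_m2 < 0 or self.lever_arm_m < 0:
            raise ValueError("IAP parameters must be non-negative")


@dataclass
class TrunkChain:
    """Unposed chain: segments, fascicles and appendage data for one subject."""

    subject: SubjectProfile
    params: ParameterSet
    segments: dict[str, Segment]
    fascicles: tuple[MuscleFascicle, ...]
    geometry: dict[str, Any]
    seg_mass: dict[str, float]
    iap: IAPConfig
    stiffness: np.ndarray  # N.m/deg per plane (flexion, lateral, axial)

    @property
    def joint_count(self) -> int:
        return len(JOINT_ORDER)


@dataclass
class PosedModel:
    """World-frame geometry of a posed chain plus external load information."""

    chain: TrunkChain
    posture: Posture
    frames: dict[str, np.ndarray]        # segment -> 3x3 rotation
    origins: dict[str, np.ndarray]       # segment -> world origin (proximal joint)
    joint_centers: dict[str, np.ndarray]
    point_masses: list[tuple[str, float, np.ndarray]]  # (name, kg, world CoM)
    fascicle_points: dict[str, np.ndarray]  # world path points, caudal first
    hand_loads: tuple[HandLoad, ...]
    gravity: np.ndarray
    iap_point: np.ndarray                # world application point of the IAP force
    iap_axis: np.ndarray                 # world direction of the IAP force (unit)

    def joint_frame(self, joint: str) -> np.ndarray:
        """Frame of the segment inferior to the joint (S1 frame for L5S1)."""
        inferior = SEGMENT_ORDER[JOINT_ORDER.index(joint)]
        return self.frames[inferior]


def _scaled(xyz: Sequence[float], scale: float) -> np.ndarray:
    return np.asarray(xyz, dtype=float) * scale


def build_chain(
    subject: SubjectProfile, params: ParameterSet, geometry: Any = None
) -> TrunkChain:
    """Assemble the subject-scaled chain.

    Segment lengths are stature fractions from the geometry config; masses
    come from the variant's segment-mass table (the lumbar row is divided
    equally over the five lumbar bodies); fascicle strengths are
    PCSA x weight x specific tension x strength scale.
    """
    geo = load_config(geometry, "geometry.yaml")
    frac = geo["segment_fractions"]
    scale = subject.stature / geo["reference_stature"]
    masses = segment_masses(params.mass_table, subject.mass)

    lumbar_h = frac["lumbar_height"] * subject.stature / 5.0
    thorax_h = frac["thorax_height"] * subject.stature

    segments: dict[str, Segment] = {
        "pelvis": Segment(
            "pelvis",
            masses["pelvis"],
            0.10 * subject.stature,
            com_offset=np.array([0.0, 0.0, -0.05 * subject.stature]),
        )
    }
    lumbar_com_x = geo["com_offsets"]["lumbar_anterior"] * scale
    for name in ("L5", "L4", "L3", "L2", "L1"):
        segments[name] = Segment(
            name,
            masses["lumbar"] / 5.0,
            lumbar_h,
            com_offset=np.array([lumbar_com_x, 0.0, lumbar_h / 2.0]),
        )
    segments["thorax"] = Segment(
        "thorax", masses["thorax"], thorax_h, com_offset=_scaled(geo["com_offsets"]["thorax"], scale)
    )

    required = {"pelvis", "L5", "L4", "L3", "L2", "L1", "thorax"}
    fascicles: list[MuscleFascicle] = []
    weights_check: dict[str, float] = {}
    for entry in geo["fascicles"]:
        anchors = [entry["origin"], *entry.get("via", []), entry["insertion"]]
        for anchor in anchors:
            if anchor["segment"] not in required:
                raise ValueError(
                    f"fascicle {entry['name']} anchors on unknown segment "
                    f"{anchor['segment']!r}"
                )
        muscle = entry["muscle"]
        pcsa = params.pcsa_table[muscle] * entry["weight"]
        strength = muscle_strength(pcsa, params.specific_tension, params.strength_scale)
        weights_check[muscle] = weights_check.get(muscle, 0.0) + entry["weight"]
        for side, mirror in (("left", 1.0), ("right", -1.0)):
            path = tuple(
                (
                    a["segment"],
                    _scaled(a["xyz"], scale) * np.array([1.0, mirror, 1.0]),
                )
                for a in anchors
            )
            fascicles.append(
                MuscleFascicle(
                    name=f"{entry['name']}_{side[0]}",
                    muscle=muscle,
                    group=entry["group"],
                    side=side,
                    pcsa=pcsa,
                    strength=strength,
                    path=path,
                )
            )
    for muscle, total in weights_check.items():
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"fascicle PCSA weights for {muscle} sum to {total}, expected 1"
            )

    iap_cfg = geo["iap"]
    stiff = geo["stiffness_nm_per_deg"]
    return TrunkChain(
        subject=subject,
        params=params,
        segments=segments,
        fascicles=tuple(fascicles),
        geometry=geo,
        seg_mass=masses,
        iap=IAPConfig(
            max_pressure_kpa=iap_cfg["max_pressure_kpa"],
            effective_area_m2=iap_cfg["effective_area_m2"],
            lever_arm_m=iap_cfg["lever_arm_m"],
        ),
        stiffness=np.array(
            [stiff["flexion"], stiff["lateral"], stiff["axial"]], dtype=float
        ),
    )


def pose_chain(
    chain: TrunkChain,
    posture: Posture,
    hand_loads: Sequence[HandLoad] = (),
) -> PosedModel:
    """Forward kinematics: compose segment frames by successive intrinsic
    rotations about the joint centres; place appendage masses and loads."""
    rotations = np.asarray(posture.joint_rotations, dtype=float)
    if not np.all(np.isfinite(rotations)):
        raise ValueError("posture joint rotations must be finite")
    geo = chain.geometry
    scale = chain.subject.stature / geo["reference_stature"]
    g = geo["gravity"]
    gravity = np.array([0.0, 0.0, -g])

    l5s1_world = np.array(
        [0.0, 0.0, geo["segment_fractions"]["l5s1_height"] * chain.subject.stature]
    )

    frames: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    joint_centers: dict[str, np.ndarray] = {}

    pelvis_R = euler_to_matrix(np.asarray(posture.pelvis_angles, dtype=float))
    frames["pelvis"] = pelvis_R
    origins["pelvis"] = l5s1_world

    parent_R, parent_origin = pelvis_R, l5s1_world
    for j, joint in enumerate(JOINT_ORDER):
        seg_name = SEGMENT_ORDER[j + 1]
        # Posture stores joints cranial-first (T12L1..L5S1); chain runs caudal-up.
        angles = rotations[len(JOINT_ORDER) - 1 - j]
        joint_centers[joint] = parent_origin
        R = parent_R @ euler_to_matrix(angles)
        frames[seg_name] = R
        origins[seg_name] = parent_origin
        parent_R = R
        parent_origin = parent_origin + R @ np.array(
            [0.0, 0.0, chain.segments[seg_name].length]
        )

    point_masses: list[tuple[str, float, np.ndarray]] = []
    for name in ("L5", "L4", "L3", "L2", "L1", "thorax"):
        seg = chain.segments[name]
        com = origins[name] + frames[name] @ seg.com_offset
        point_masses.append((name, seg.mass, com))
    head_com = origins["thorax"] + frames["thorax"] @ _scaled(
        geo["com_offsets"]["head"], scale
    )
    point_masses.append(("head", chain.seg_mass["head"], head_com))

    # Arms: CoMs on the shoulder->hand line, one arm per hand target.
    shoulder_local = _scaled(geo["com_offsets"]["shoulder"], scale)
    hands = [np.asarray(p, dtype=float) for p in posture.hand_positions]
    if not hands:  # arms hanging at the sides
        hands = [
            origins["pelvis"] + pelvis_R @ np.array([0.02, s * 0.20, -0.25]) * scale
            for s in (1.0, -1.0)
        ]
    arm_frac = geo["arm_com_fractions"]
    n_arms = len(hands)
    for k, hand in enumerate(hands):
        side = 1.0 if (n_arms == 1 or k == 0) else -1.0
        if n_arms == 1:
            side = -1.0  # a single target is treated as the right hand
        shoulder = origins["thorax"] + frames["thorax"] @ (
            shoulder_local * np.array([1.0, side, 1.0])
        )
        for seg_name, fr in (
            ("upper_arms", arm_frac["upper_arm"]),
            ("lower_arms", arm_frac["lower_arm"]),
            ("hands", arm_frac["hand"]),
        ):
            m = chain.seg_mass[seg_name] / max(n_arms, 2)
            com = shoulder + fr * (hand - shoulder)
            point_masses.append((f"{seg_name}_{k}", m, com))
    if n_arms == 1:
        # the unloaded arm hangs at the side
        hang = origins["pelvis"] + pelvis_R @ np.array([0.02, 0.20, -0.25]) * scale
        shoulder = origins["thorax"] + frames["thorax"] @ shoulder_local
        for seg_name, fr in (
            ("upper_arms", arm_frac["upper_arm"]),
            ("lower_arms", arm_frac["lower_arm"]),
            ("hands", arm_frac["hand"]),
        ):
            m = chain.seg_mass[seg_name] / 2.0
            point_masses.append((f"{seg_name}_free", m, shoulder + fr * (hang - shoulder)))

    fascicle_points: dict[str, np.ndarray] = {}
    for fas in chain.fascicles:
        fascicle_points[fas.name] = np.array(
            [origins[seg] + frames[seg] @ xyz for seg, xyz in fas.path]
        )

    iap_point = origins["thorax"] + frames["thorax"] @ np.array(
        [chain.iap.lever_arm_m * scale, 0.0, 0.0]
    )
    iap_axis = frames["thorax"] @ np.array([0.0, 0.0, 1.0])

    return PosedModel(
        chain=chain,
        posture=posture,
        frames=frames,
        origins=origins,
        joint_centers=joint_centers,
        point_masses=point_masses,
        fascicle_points=fascicle_points,
        hand_loads=tuple(hand_loads),
        gravity=gravity,
        iap_point=iap_point,
        iap_axis=iap_axis,
    )


def _superior_masses(posed: PosedModel, joint: str) -> list[tuple[float, np.ndarray]]:
    """Point masses carried above (superior to) the given joint."""
    j = JOINT_ORDER.index(joint)
    spine_above = set(SEGMENT_ORDER[j + 1 :])
    items = []
    for name, mass, com in posed.point_masses:
        base = name.split("_")[0]
        if name in spine_above or base in ("head", "upper", "lower", "hands"):
            items.append((mass, com))
    return items


def gravity_moment(posed: PosedModel, joint: str) -> np.ndarray:
    """Moment (N.m, world frame) of segment weights above the joint."""
    c = posed.joint_centers[joint]
    total = np.zeros(3)
    for mass, com in _superior_masses(posed, joint):
        total += np.cross(com - c, mass * posed.gravity)
    return total


def hand_load_moment(load: HandLoad, posed: PosedModel, joint: str) -> np.ndarray:
    """Moment (N.m, world frame) of the hand load about a joint."""
    c = posed.joint_centers[joint]
    total = np.zeros(3)
    for mass, pos in load.point_masses():
        total += np.cross(pos - c, mass * posed.gravity)
    return total


def iap_extensor_moment(pressure_kpa: float, cfg: IAPConfig) -> float:
    """Extension moment (N.m) produced by the capped intra-abdominal pressure."""
    if pressure_kpa < 0:
        raise ValueError("pressure must be non-negative")
    p = min(pressure_kpa, cfg.max_pressure_kpa)
    return p * 1000.0 * cfg.effective_area_m2 * cfg.lever_arm_m


def iap_moment_column(posed: PosedModel, joint: str) -> np.ndarray:
    """World-frame moment about a joint per kPa of IAP (point-force model)."""
    c = posed.joint_centers[joint]
    area = posed.chain.iap.effective_area_m2
    return np.cross(posed.iap_point - c, 1000.0 * area * posed.iap_axis)


def passive_joint_moment(rotation_deg: np.ndarray, stiffness: np.ndarray) -> np.ndarray:
    """Linear passive moment, per plane, opposing the joint rotation."""
    rotation = np.asarray(rotation_deg, dtype=float)
    k = np.asarray(stiffness, dtype=float)
    if np.any(k < 0):
        raise ValueError("stiffness must be non-negative")
    return -k * rotation


def moment_arm_matrix(posed: PosedModel, joint: str) -> np.ndarray:
    """(n_fascicles x 3) world-frame moment arms about a joint (m).

    Row k is (insertion - joint centre) x unit pull direction for fascicles
    crossing the joint, zero otherwise.  The pull direction points from the
    insertion toward the origin (force exerted on the superior body).
    """
    j = JOINT_ORDER.index(joint)
    c = posed.joint_centers[joint]
    rows = np.zeros((len(posed.chain.fascicles), 3))
    for k, fas in enumerate(posed.chain.fascicles):
        if not fas.crosses_joint(j):
            continue
        below, above = fas.crossing_pair(j)
        points = posed.fascicle_points[fas.name]
        line = points[below] - points[above]
        length = np.linalg.norm(line)
        if length < 1e-9:
            raise ValueError(f"fascicle {fas.name} has degenerate (zero) length")
        rows[k] = np.cross(points[above] - c, line / length)
    return rows


def fascicle_length(posed: PosedModel, name: str) -> float:
    """Total polyline length of a fascicle's path (m)."""
    points = posed.fascicle_points[name]
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def fascicle_force_vectors(
    posed: PosedModel, forces: np.ndarray, joint: str = "L5S1"
) -> np.ndarray:
    """World-frame force each fascicle exerts on the body above ``joint``
    (zero for fascicles not crossing it)."""
    j = JOINT_ORDER.index(joint)
    vecs = np.zeros((len(posed.chain.fascicles), 3))
    for k, fas in enumerate(posed.chain.fascicles):
        if not fas.crosses_joint(j):
            continue
        below, above = fas.crossing_pair(j)
        points = posed.fascicle_points[fas.name]
        line = points[below] - points[above]
        vecs[k] = forces[k] * line / np.linalg.norm(line)
    return vecs
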