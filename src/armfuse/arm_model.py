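"""Upper-limb kinematic chains: forward kinematics and exact propagation of
angular velocity and linear acceleration down the segment tree.

Frame and pose conventions
--------------------------
The root (chest) frame has x pointing anteriorly, y to the subject's left
and z up.  The chest is treated as a steady rigid body fixed at the origin.
In the reference N-pose (all joint angles zero) every segment frame is
aligned with the root frame and the arm hangs straight down, so the wrist
sits at ``shoulder_centre + (0, 0, -(L_ua + L_fa))``.

The default five degree-of-freedom arm actuates, in order,

====  =====================================  ==================
idx   functional movement                    axis at N-pose
====  =====================================  ==================
0     shoulder flexion/extension  (SFE)      (0, -1, 0)
1     shoulder abduction/adduction (SAA)     (1, 0, 0)
2     shoulder internal rotation  (SIR)      (0, 0, 1)
3     elbow flexion/extension     (EFE)      (0, -1, 0)
4     forearm pronation/supination (EPS)     (0, 0, 1)
====  =====================================  ==================

so each scripted functional movement drives exactly one coordinate.  Signs
are chosen so positive SFE/EFE move the wrist anteriorly and positive SAA
abducts the (left) arm laterally.

Rates are produced by an exact frame-to-frame recursion (no numerical
differentiation): for a child frame related to its parent by
``A_pre ∘ Rot(axis, q) ∘ A_post``,

* body angular velocity:    ``w_c = R_relᵀ w_p + c q̇``  with ``c = R_postᵀ axis``,
* body angular acceleration: ``ẇ_c = R_relᵀ ẇ_p − (c q̇) × (R_relᵀ w_p) + c q̈``,
* linear acceleration of the child origin adds the rigid-offset terms
  ``α × d + w × (w × d)`` evaluated with the rates of the frame each offset
  is rigid in.

The same recursion serves the simulator and the model-based filters, and is
validated against finite differences of the forward kinematics in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import (
    DhRow,
    RigidTransform,
    rotation_about_axis,
    skew,
)

__all__ = [
    "Joint",
    "LimbSegment",
    "JointState",
    "SegmentSignal",
    "ChainSignals",
    "KinematicChain",
    "DhChain",
    "default_arm_chain",
    "build_dh_from_chain",
    "forward_kinematics",
    "segment_angular_velocity",
    "propagate_linear_acceleration",
    "MOVEMENT_JOINT",
]

#: functional movement -> joint name in the default chain
MOVEMENT_JOINT = {
    "SFE": "sfe",
    "SAA": "saa",
    "SIR": "sir",
    "EFE": "efe",
    "EPS": "eps",
}


@dataclass(frozen=True)
class Joint:
    """Revolute joint: rotation about ``axis`` (unit vector, local frame)."""

    name: str
    axis: tuple[float, float, float]


@dataclass
class LimbSegment:
    """One rigid segment: attached to ``parent`` at ``offset`` (metres, in the
    parent frame), rotated by its ``joints`` applied in order."""

    name: str
    parent: str | None
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    joints: tuple[Joint, ...] = ()
    length: float = 0.0


@dataclass
class JointState:
    """Joint coordinates and their first two time derivatives."""

    q: np.ndarray
    qdot: np.ndarray
    qddot: np.ndarray

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.qdot = np.atleast_1d(np.asarray(self.qdot, dtype=float))
        self.qddot = np.atleast_1d(np.asarray(self.qddot, dtype=float))
        if not (self.q.shape == self.qdot.shape == self.qddot.shape):
            raise ValueError("q, qdot, qddot must share one shape")


@dataclass
class SegmentSignal:
    """Per-segment kinematic signals over a batch axis (time or sigma points).

    ``R`` (B,3,3) body-to-root rotation; ``pos`` (B,3) origin in root frame;
    ``omega``/``alpha`` (B,3) body-frame angular velocity/acceleration;
    ``acc`` (B,3) root-frame linear acceleration of the origin (gravity-free).
    """

    R: np.ndarray
    pos: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    acc: np.ndarray


@dataclass
class ChainSignals:
    segments: dict[str, SegmentSignal]

    def __getitem__(self, name: str) -> SegmentSignal:
        return self.segments[name]


def _cross(a, b):
    # inlined cross product: avoids np.cross's axis-normalization overhead
    # on the many small (B,3) batches in the recursion hot path
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


@dataclass
class _Unit:
    parent: int  # index into the unit list; -1 is the world frame
    pre: RigidTransform
    axis: np.ndarray | None
    joint: int | None
    post: RigidTransform
    label: str | None


class _UnitChain:
    """Shared machinery: a tree of elementary frames with batched recursions."""

    def __init__(self, units: list[_Unit], joint_names: list[str], wrist: str):
        for k, u in enumerate(units):
            if u.parent >= k:
                raise ValueError("units must be ordered parent before child")
        self._units = units
        self.joint_names = list(joint_names)
        self.wrist_name = wrist
        self.segment_names = [u.label for u in units if u.label is not None]
        self._parents = self._segment_parents()

    @property
    def ndof(self) -> int:
        return len(self.joint_names)

    def _segment_parents(self) -> dict[str, str | None]:
        parents: dict[str, str | None] = {}
        for u in self._units:
            if u.label is None:
                continue
            p = u.parent
            while p != -1 and self._units[p].label is None:
                p = self._units[p].parent
            parents[u.label] = None if p == -1 else self._units[p].label
        return parents

    def parent_of(self, name: str) -> str | None:
        return self._parents[name]

    # -- kinematic recursion ------------------------------------------------

    def signals(self, Q, Qd=None, Qdd=None, root_acc=None) -> ChainSignals:
        """Batched poses and exact rates for every labelled segment.

        ``Q``/``Qd``/``Qdd``: (B, ndof) joint angles and derivatives (missing
        derivatives are taken as zero).  ``root_acc``: (3,) or (B,3) linear
        acceleration of the root (defaults to zero: steady chest).
        """
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        B, n = Q.shape
        if n != self.ndof:
            raise ValueError(f"expected {self.ndof} joint coordinates, got {n}")
        Qd = np.zeros_like(Q) if Qd is None else np.atleast_2d(np.asarray(Qd, dtype=float))
        Qdd = np.zeros_like(Q) if Qdd is None else np.atleast_2d(np.asarray(Qdd, dtype=float))
        if Qd.shape != Q.shape or Qdd.shape != Q.shape:
            raise ValueError("Q, Qd, Qdd must share one shape")

        eye = np.broadcast_to(np.eye(3), (B, 3, 3))
        zero = np.zeros((B, 3))
        if root_acc is None:
            acc0 = zero
        else:
            acc0 = np.broadcast_to(np.asarray(root_acc, dtype=float), (B, 3))

        Rs, ps, ws, dws, accs = [], [], [], [], []
        out: dict[str, SegmentSignal] = {}

        for u in self._units:
            if u.parent == -1:
                R0p, pp, wp, dwp, ap = eye, zero, zero, zero, acc0
            else:
                R0p, pp, wp, dwp, ap = (
                    Rs[u.parent], ps[u.parent], ws[u.parent], dws[u.parent], accs[u.parent],
                )

            if u.axis is None:
                Rfix = u.pre.R @ u.post.R
                R_rel = np.broadcast_to(Rfix, (B, 3, 3))
                wk = np.einsum("ij,bj->bi", Rfix.T, wp)
                dwk = np.einsum("ij,bj->bi", Rfix.T, dwp)
            else:
                q = Q[:, u.joint]
                qd = Qd[:, u.joint]
                qdd = Qdd[:, u.joint]
                S = skew(u.axis)
                S2 = S @ S
                Rod = (
                    np.eye(3)
                    + np.sin(q)[:, None, None] * S
                    + (1.0 - np.cos(q))[:, None, None] * S2
                )
                R_rel = np.einsum("ij,bjk,kl->bil", u.pre.R, Rod, u.post.R)
                c = u.post.R.T @ u.axis  # joint axis seen from the child frame
                wp_in_c = np.einsum("bji,bj->bi", R_rel, wp)
                dwp_in_c = np.einsum("bji,bj->bi", R_rel, dwp)
                cqd = c[None, :] * qd[:, None]
                wk = wp_in_c + cqd
                dwk = dwp_in_c - _cross(cqd, wp_in_c) + c[None, :] * qdd[:, None]

            R0k = np.einsum("bij,bjk->bik", R0p, R_rel)

            # pre.t is rigid in the parent frame; post.t is expressed in the
            # post-rotation frame, which shares the child's angular rates
            d_pre_w = np.einsum("bij,j->bi", R0p, u.pre.t)
            t_post_c = u.post.R.T @ u.post.t
            d_post_w = np.einsum("bij,j->bi", R0k, t_post_c)
            pk = pp + d_pre_w + d_post_w

            wp_w = np.einsum("bij,bj->bi", R0p, wp)
            ap_w = np.einsum("bij,bj->bi", R0p, dwp)
            wk_w = np.einsum("bij,bj->bi", R0k, wk)
            ak_w = np.einsum("bij,bj->bi", R0k, dwk)

            acck = (
                ap
                + _cross(ap_w, d_pre_w) + _cross(wp_w, _cross(wp_w, d_pre_w))
                + _cross(ak_w, d_post_w) + _cross(wk_w, _cross(wk_w, d_post_w))
            )

            Rs.append(R0k)
            ps.append(pk)
            ws.append(wk)
            dws.append(dwk)
            accs.append(acck)
            if u.label is not None:
                out[u.label] = SegmentSignal(R0k, pk, wk, dwk, acck)

        return ChainSignals(out)

    def forward(self, q) -> tuple[dict[str, RigidTransform], np.ndarray]:
        """Single-pose forward kinematics: segment poses + wrist position."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any(np.abs(q) > 2 * np.pi):
            raise ValueError("joint angles outside ±2π")
        sig = self.signals(q[None, :])
        poses = {
            name: RigidTransform(s.R[0], s.pos[0]) for name, s in sig.segments.items()
        }
        return poses, sig[self.wrist_name].pos[0]


class KinematicChain(_UnitChain):
    """Arm chain parametrized by named single-axis revolute joints."""

    def __init__(self, segments: list[LimbSegment], wrist: str = "wrist"):
        names = [s.name for s in segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        idx_of_label: dict[str, int] = {}
        units: list[_Unit] = []
        joint_names: list[str] = []
        for seg in segments:
            if seg.parent is None:
                parent = -1
            elif seg.parent in idx_of_label:
                parent = idx_of_label[seg.parent]
            else:
                raise ValueError(
                    f"segment {seg.name!r} listed before its parent {seg.parent!r}"
                )
            offset = RigidTransform(np.eye(3), np.asarray(seg.offset, dtype=float))
            if not seg.joints:
                units.append(_Unit(parent, offset, None, None, RigidTransform(), seg.name))
            else:
                for j, joint in enumerate(seg.joints):
                    axis = np.asarray(joint.axis, dtype=float)
                    axis = axis / np.linalg.norm(axis)
                    pre = offset if j == 0 else RigidTransform()
                    par = parent if j == 0 else len(units) - 1
                    label = seg.name if j == len(seg.joints) - 1 else None
                    units.append(_Unit(par, pre, axis, len(joint_names), RigidTransform(), label))
                    joint_names.append(joint.name)
            idx_of_label[seg.name] = len(units) - 1
        super().__init__(units, joint_names, wrist)
        self.segments = list(segments)

    def to_config(self) -> dict:
        return {
            "schema": "armfuse-chain/1",
            "wrist": self.wrist_name,
            "segments": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "offset_m": [float(v) for v in s.offset],
                    "length_m": float(s.length),
                    "joints": [
                        {"name": j.name, "axis": [float(v) for v in j.axis]}
                        for j in s.joints
                    ],
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "KinematicChain":
        if cfg.get("schema") != "armfuse-chain/1":
            raise ValueError("unknown chain config schema")
        segs = [
            LimbSegment(
                name=s["name"],
                parent=s["parent"],
                offset=tuple(s["offset_m"]),
                joints=tuple(
                    Joint(j["name"], tuple(j["axis"])) for j in s.get("joints", ())
                ),
                length=s.get("length_m", 0.0),
            )
            for s in cfg["segments"]
        ]
        return cls(segs, wrist=cfg.get("wrist", "wrist"))


class DhChain(_UnitChain):
    """Serial chain in classic (distal) Denavit-Hartenberg form.

    Each row rotates about the local z axis; row ``k`` in ``frozen`` is held
    at a fixed angle and excluded from the joint vector (the two clavicle
    rows of the default seven-row arm are frozen at zero).  ``segment_rows``
    maps row index -> (segment name, alignment rotation) attaching labelled
    segment frames, and ``landmarks`` adds fixed child frames (the wrist).
    """

    def __init__(
        self,
        base: RigidTransform,
        rows: list[DhRow],
        joint_names: list[str],
        frozen: dict[int, float] | None = None,
        segment_rows: dict[int, tuple[str, RigidTransform]] | None = None,
        landmarks: list[tuple[str, str, np.ndarray]] | None = None,
        wrist: str = "wrist",
        root_label: str = "chest",
    ):
        frozen = dict(frozen or {})
        segment_rows = dict(segment_rows or {})
        ez = np.array([0.0, 0.0, 1.0])
        units: list[_Unit] = [
            _Unit(-1, RigidTransform(), None, None, RigidTransform(), root_label),
            _Unit(0, base, None, None, RigidTransform(), None),
        ]
        label_unit: dict[str, int] = {root_label: 0}
        row_unit: dict[int, int] = {}
        active = 0
        for k, row in enumerate(rows):
            parent = row_unit[k - 1] if k else 1
            post = RigidTransform(
                rotation_about_axis([1.0, 0.0, 0.0], row.alpha),
                np.array([row.a, 0.0, row.d]),
            )
            if k in frozen:
                pre = RigidTransform(
                    rotation_about_axis(ez, frozen[k] + row.theta_offset), np.zeros(3)
                )
                units.append(_Unit(parent, pre, None, None, post, None))
            else:
                pre = RigidTransform(rotation_about_axis(ez, row.theta_offset), np.zeros(3))
                units.append(_Unit(parent, pre, ez.copy(), active, post, None))
                active += 1
            row_unit[k] = len(units) - 1
            if k in segment_rows:
                name, align = segment_rows[k]
                units.append(
                    _Unit(row_unit[k], align, None, None, RigidTransform(), name)
                )
                label_unit[name] = len(units) - 1
        for name, parent_seg, offset in landmarks or []:
            units.append(
                _Unit(
                    label_unit[parent_seg],
                    RigidTransform(np.eye(3), np.asarray(offset, dtype=float)),
                    None,
                    None,
                    RigidTransform(),
                    name,
                )
            )
        if active != len(joint_names):
            raise ValueError("joint_names must name every non-frozen row")
        self.base = base
        self.rows = list(rows)
        super().__init__(units, joint_names, wrist)


# ---------------------------------------------------------------------------
# default chains
# ---------------------------------------------------------------------------

def default_arm_chain(
    upper_arm: float = 0.30,
    forearm: float = 0.25,
    acromion: tuple[float, float, float] = (0.0, 0.20, 0.25),
    shoulder_drop: float = 0.045,
) -> KinematicChain:
    """Five-DoF left-arm chain rooted in a steady chest.

    The shoulder joint centre sits ``shoulder_drop`` metres (default 4.5 cm)
    below the acromion along the vertical axis; default segment lengths are
    0.30 m (upper arm) and 0.25 m (forearm).
    """
    shoulder = (acromion[0], acromion[1], acromion[2] - shoulder_drop)
    return KinematicChain(
        [
            LimbSegment("chest", None),
            LimbSegment(
                "upper_arm",
                "chest",
                offset=shoulder,
                joints=(
                    Joint("sfe", (0.0, -1.0, 0.0)),
                    Joint("saa", (1.0, 0.0, 0.0)),
                    Joint("sir", (0.0, 0.0, 1.0)),
                ),
                length=upper_arm,
            ),
            LimbSegment(
                "forearm",
                "upper_arm",
                offset=(0.0, 0.0, -upper_arm),
                joints=(
                    Joint("efe", (0.0, -1.0, 0.0)),
                    Joint("eps", (0.0, 0.0, 1.0)),
                ),
                length=forearm,
            ),
            LimbSegment("wrist", "forearm", offset=(0.0, 0.0, -forearm)),
        ]
    )


def build_dh_from_chain(chain: KinematicChain, clavicle: bool = True) -> DhChain:
    """Denavit-Hartenberg form of a serial single-axis chain.

    Walks the chain's joints at the reference pose, solves each row's twist
    and angle offset so consecutive z axes coincide with the joint axes, and
    records fixed alignment rotations restoring the original segment frames
    (so sensor mountings transfer unchanged).  With ``clavicle=True`` two
    extra rows (protraction about z, elevation about x, both frozen at zero)
    are prepended at the shoulder centre, giving the seven-row arm whose two
    clavicle coordinates stay at zero by default.
    """
    poses, _ = chain.forward(np.zeros(chain.ndof))
    joints_w: list[tuple[str, np.ndarray, np.ndarray, str | None]] = []
    for seg in chain.segments:
        if not seg.joints:
            continue
        origin = poses[seg.name].t  # joints of one segment share the origin
        for j, joint in enumerate(seg.joints):
            label = seg.name if j == len(seg.joints) - 1 else None
            joints_w.append((joint.name, np.asarray(joint.axis, float), origin, label))

    if clavicle:
        base_origin = joints_w[0][2]
        joints_w = [
            ("clav_protraction", np.array([0.0, 0.0, 1.0]), base_origin, None),
            ("clav_elevation", np.array([1.0, 0.0, 0.0]), base_origin, None),
        ] + joints_w
        frozen_idx: dict[int, float] = {0: 0.0, 1: 0.0}
    else:
        frozen_idx = {}

    # base frame: z along the first joint axis
    z = joints_w[0][1] / np.linalg.norm(joints_w[0][1])
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, z)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    B = np.column_stack([x, np.cross(z, x), z])
    base = RigidTransform(B, joints_w[0][2])

    rows: list[DhRow] = []
    names: list[str] = []
    segment_rows: dict[int, tuple[str, RigidTransform]] = {}
    G = B.copy()  # reference-pose orientation of the current row frame
    origin = joints_w[0][2].copy()
    for k, (jname, _axis, _origin, label) in enumerate(joints_w):
        if k + 1 < len(joints_w):
            u = G.T @ joints_w[k + 1][1]
            sin_a = float(np.hypot(u[0], u[1]))
            alpha = float(np.arctan2(sin_a, u[2]))
            theta_off = float(np.arctan2(u[0], -u[1])) if sin_a > 1e-12 else 0.0
            delta = G.T @ (joints_w[k + 1][2] - origin)
            d = float(delta[2])
            a_len = float(np.hypot(delta[0], delta[1]))
            if a_len > 1e-12:
                t_dir = float(np.arctan2(delta[1], delta[0]))
                if sin_a <= 1e-12:
                    theta_off = t_dir
                elif abs(np.remainder(t_dir - theta_off + np.pi, 2 * np.pi) - np.pi) > 1e-9:
                    raise ValueError(
                        f"chain not DH-representable at joint {jname!r}: in-plane "
                        "offset not aligned with the solved x axis"
                    )
            rows.append(DhRow(a=a_len, alpha=alpha, d=d, theta_offset=theta_off))
            G = G @ rotation_about_axis([0, 0, 1], theta_off) @ rotation_about_axis([1, 0, 0], alpha)
            origin = joints_w[k + 1][2]
        else:
            rows.append(DhRow())
        names.append(jname)
        if label is not None:
            # fixed transform restoring the source segment frame (rotation and
            # origin) from the row frame; rigid in the same segment, so valid
            # at every pose
            segment_rows[k] = (
                label,
                RigidTransform(G.T @ poses[label].R, G.T @ (poses[label].t - origin)),
            )

    active_names = [nm for i, nm in enumerate(names) if i not in frozen_idx]
    landmarks = [
        (seg.name, seg.parent, np.asarray(seg.offset, float))
        for seg in chain.segments
        if not seg.joints and seg.parent is not None
    ]
    return DhChain(
        base,
        rows,
        active_names,
        frozen=frozen_idx,
        segment_rows=segment_rows,
        landmarks=landmarks,
        wrist=chain.wrist_name,
    )


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def forward_kinematics(chain: _UnitChain, q) -> tuple[dict[str, RigidTransform], np.ndarray]:
    """Segment poses in the root frame and the wrist position for angles ``q``."""
    return chain.forward(q)


def segment_angular_velocity(chain: _UnitChain, q, qdot) -> dict[str, np.ndarray]:
    """Body-frame angular velocity of every segment (rad/s)."""
    q = np.atleast_1d(np.asarray(q, float))
    qdot = np.atleast_1d(np.asarray(qdot, float))
    if q.shape != qdot.shape or q.shape != (chain.ndof,):
        raise ValueError("q/qdot must match the chain DoF count")
    sig = chain.signals(q[None, :], qdot[None, :])
    return {name: s.omega[0] for name, s in sig.segments.items()}


def propagate_linear_acceleration(
    chain: _UnitChain,
    poses: dict[str, RigidTransform],
    omega_world: dict[str, np.ndarray],
    alpha_world: dict[str, np.ndarray],
    root_acc=None,
) -> dict[str, np.ndarray]:
    """Root-frame linear acceleration of every segment origin, root-to-leaves.

    Implements the hierarchical-tree propagation
    ``la_child = la_parent + [S(alpha) + S(omega)²] · d`` where ``d`` is the
    root-frame offset from the parent origin to the child origin; the offset
    is rigid in the parent segment, so the parent's angular rates apply.
    """
    la: dict[str, np.ndarray] = {}
    for name in chain.segment_names:
        parent = chain.parent_of(name)
        if parent is None:
            la[name] = np.zeros(3) if root_acc is None else np.asarray(root_acc, float)
            continue
        if parent not in la:
            raise ValueError(f"segment {name!r} visited before its parent {parent!r}")
        d = poses[name].t - poses[parent].t
        w = np.asarray(omega_world[parent], float)
        al = np.asarray(alpha_world[parent], float)
        la[name] = la[parent] + np.cross(al, d) + np.cross(w, np.cross(w, d))
    return la
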