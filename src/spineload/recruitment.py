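"""Static muscle recruitment by cubic-stress minimization and L5-S1 loads.

At each of the six lumbar joints the three moment components of Newton's
(static) equations must vanish.  Muscles outnumber equations, so forces are
resolved by minimizing the sum of cubed muscle stresses,

    min  sum_i (f_i / N_i)^3   s.t.   A f + a_iap p + M_passive + M_ext = 0,
                                       0 <= f_i <= N_i,  0 <= p <= p_max,

where N_i are the fascicle strengths, A the geometric moment-arm matrix and
p the intra-abdominal pressure (a bounded auxiliary actuator with zero
objective cost).  In activity variables x_i = f_i/N_i the objective
sum x_i^3 is strictly convex on x >= 0 and the constraints are linear, so the
muscle-force solution is unique; no tie-breaking is needed.

Joint reaction forces resolve translational equilibrium; the L5-S1 load is
reported as compression along the S1 superior axis plus anteroposterior and
mediolateral shear (resultant shear = their Euclidean norm), in N and %BW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import optimize

from .model import (
    JOINT_ORDER,
    PosedModel,
    fascicle_force_vectors,
    gravity_moment,
    hand_load_moment,
    iap_moment_column,
    passive_joint_moment,
    moment_arm_matrix,
)

GRAVITY = 9.81


class InfeasibleRecruitmentError(RuntimeError):
    """Raised when no admissible muscle forces can balance the net moments."""

    def __init__(self, joint: str, plane: str, deficit: float):
        self.joint = joint
        self.plane = plane
        self.deficit = deficit
        super().__init__(
            f"recruitment infeasible: {deficit:.2f} N.m unbalanced at joint "
            f"{joint} ({plane} plane)"
        )


@dataclass
class RecruitmentProblem:
    """Assembled equilibrium problem for one posed model."""

    joints: tuple[str, ...]
    demand: np.ndarray          # (6, 3) moments the actuators must produce
    arm_matrices: np.ndarray    # (6, n_fascicles, 3)
    strengths: np.ndarray       # (n_fascicles,)
    iap_columns: np.ndarray     # (6, 3) moment per kPa
    iap_max_kpa: float
    fascicle_names: tuple[str, ...]

    def to_dict(self) -> dict[str, Any]:
        return {
            "joints": list(self.joints),
            "demand": self.demand.tolist(),
            "arm_matrices": self.arm_matrices.tolist(),
            "strengths": self.strengths.tolist(),
            "iap_columns": self.iap_columns.tolist(),
            "iap_max_kpa": self.iap_max_kpa,
            "fascicle_names": list(self.fascicle_names),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RecruitmentProblem":
        return cls(
            joints=tuple(d["joints"]),
            demand=np.asarray(d["demand"], dtype=float),
            arm_matrices=np.asarray(d["arm_matrices"], dtype=float),
            strengths=np.asarray(d["strengths"], dtype=float),
            iap_columns=np.asarray(d["iap_columns"], dtype=float),
            iap_max_kpa=float(d["iap_max_kpa"]),
            fascicle_names=tuple(d["fascicle_names"]),
        )


@dataclass
class RecruitmentSolution:
    forces: np.ndarray            # N, per fascicle
    activities: np.ndarray        # force / strength, in [0, 1]
    iap_kpa: float
    residuals: np.ndarray         # (6, 3) equilibrium residual moments, N.m
    residual_rel: float           # max_j |residual_j| / max(1, |demand_j|)
    objective: float              # sum of cubed activities
    fascicle_names: tuple[str, ...]

    def activity_of(self, fascicle: str) -> float:
        return float(self.activities[self.fascicle_names.index(fascicle)])

    def to_dict(self) -> dict[str, Any]:
        return {
            "forces": self.forces.tolist(),
            "activities": self.activities.tolist(),
            "iap_kpa": self.iap_kpa,
            "residuals": self.residuals.tolist(),
            "residual_rel": self.residual_rel,
            "objective": self.objective,
            "fascicle_names": list(self.fascicle_names),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RecruitmentSolution":
        return cls(
            forces=np.asarray(d["forces"], dtype=float),
            activities=np.asarray(d["activities"], dtype=float),
            iap_kpa=float(d["iap_kpa"]),
            residuals=np.asarray(d["residuals"], dtype=float),
            residual_rel=float(d["residual_rel"]),
            objective=float(d["objective"]),
            fascicle_names=tuple(d["fascicle_names"]),
        )


@dataclass(frozen=True)
class JointLoads:
    """L5-S1 reaction decomposed in the S1 superior-endplate frame."""

    compression: float
    ap_shear: float
    ml_shear: float
    body_mass: float

    @property
    def resultant_shear(self) -> float:
        return float(np.hypot(self.ap_shear, self.ml_shear))

    @property
    def compression_bw(self) -> float:
        return normalize_bw(self.compression, self.body_mass)

    @property
    def shear_bw(self) -> float:
        return normalize_bw(self.resultant_shear, self.body_mass)


def net_joint_moments(posed: PosedModel) -> dict[str, np.ndarray]:
    """External moment (gravity + hand loads + passive) at each lumbar joint."""
    moments: dict[str, np.ndarray] = {}
    rotations = np.asarray(posed.posture.joint_rotations, dtype=float)
    n = len(JOINT_ORDER)
    for j, joint in enumerate(JOINT_ORDER):
        m = gravity_moment(posed, joint)
        for load in posed.hand_loads:
            m += hand_load_moment(load, posed, joint)
        # passive moment expressed in the inferior segment's frame
        angles = rotations[n - 1 - j]
        local = passive_joint_moment(angles, posed.chain.stiffness)
        # local planes: flexion about +Y, lateral about +X, axial about +Z
        local_vec = np.array([local[1], local[0], local[2]])
        m += posed.joint_frame(joint) @ local_vec
        moments[joint] = m
    return moments


def assemble_problem(posed: PosedModel) -> RecruitmentProblem:
    n = len(posed.chain.fascicles)
    demand = np.zeros((len(JOINT_ORDER), 3))
    arms = np.zeros((len(JOINT_ORDER), n, 3))
    iap_cols = np.zeros((len(JOINT_ORDER), 3))
    net = net_joint_moments(posed)
    for j, joint in enumerate(JOINT_ORDER):
        demand[j] = -net[joint]
        arms[j] = moment_arm_matrix(posed, joint)
        iap_cols[j] = iap_moment_column(posed, joint)
    return RecruitmentProblem(
        joints=JOINT_ORDER,
        demand=demand,
        arm_matrices=arms,
        strengths=np.array([f.strength for f in posed.chain.fascicles]),
        iap_columns=iap_cols,
        iap_max_kpa=posed.chain.iap.max_pressure_kpa,
        fascicle_names=tuple(f.name for f in posed.chain.fascicles),
    )


def _constraint_matrix(problem: RecruitmentProblem) -> tuple[np.ndarray, np.ndarray]:
    """Rows = 18 moment equations; columns = activities then IAP fraction."""
    n = len(problem.strengths)
    n_rows = problem.demand.size
    B = np.zeros((n_rows, n + 1))
    for j in range(len(problem.joints)):
        # moment of fascicle k about joint j per unit activity
        B[3 * j : 3 * j + 3, :n] = (problem.arm_matrices[j] * problem.strengths[:, None]).T
        B[3 * j : 3 * j + 3, n] = problem.iap_columns[j] * problem.iap_max_kpa
    d = problem.demand.reshape(-1)
    return B, d


def solve_recruitment(
    problem: RecruitmentProblem,
    tol: float = 1e-9,
    residual_tol: float = 1e-6,
) -> RecruitmentSolution:
    """Solve the cubic-stress recruitment problem.

    A linear-programming feasibility phase (minimum total slack) detects
    infeasible demands and provides the starting point for the convex solve
    (SLSQP with analytic gradients, trust-constr fallback).
    """
    B_full, d_full = _constraint_matrix(problem)
    n = len(problem.strengths)
    # drop all-zero equation rows (axes with no demand and no actuator):
    # they are trivially satisfied and make the constraint Jacobian singular
    nonzero = (np.abs(B_full).max(axis=1) > 0) | (np.abs(d_full) > 0)
    B, d = B_full[nonzero], d_full[nonzero]
    row_index = np.flatnonzero(nonzero)
    if np.any(~nonzero & (np.abs(d_full) > 1e-9)):
        bad = int(np.flatnonzero(~nonzero & (np.abs(d_full) > 1e-9))[0])
        raise InfeasibleRecruitmentError(
            problem.joints[bad // 3], "XYZ"[bad % 3], float(abs(d_full[bad]))
        )
    n_rows = len(d)

    # Phase 1: min sum(s+ + s-) s.t. B z + s+ - s- = d
    c = np.concatenate([np.zeros(n + 1), np.ones(2 * n_rows)])
    A_eq = np.hstack([B, np.eye(n_rows), -np.eye(n_rows)])
    bounds = [(0.0, 1.0)] * (n + 1) + [(0.0, None)] * (2 * n_rows)
    lp = optimize.linprog(c, A_eq=A_eq, b_eq=d, bounds=bounds, method="highs")
    if not lp.success:
        raise RuntimeError(f"feasibility phase failed: {lp.message}")
    slack = lp.x[n + 1 :]
    gaps = slack[:n_rows] + slack[n_rows:]
    worst = int(np.argmax(gaps))
    if gaps.sum() > max(1e-6, 1e-9 * np.abs(d).max()):
        full_row = int(row_index[worst])
        joint = problem.joints[full_row // 3]
        plane = ("X (lateral axis)", "Y (flexion axis)", "Z (axial)")[full_row % 3]
        raise InfeasibleRecruitmentError(joint, plane, float(gaps[worst]))
    z0 = lp.x[: n + 1]

    def objective(z: np.ndarray) -> float:
        return float(np.sum(z[:n] ** 3))

    def grad(z: np.ndarray) -> np.ndarray:
        g = np.zeros_like(z)
        g[:n] = 3.0 * z[:n] ** 2
        return g

    constraints = {"type": "eq", "fun": lambda z: B @ z - d, "jac": lambda z: B}
    res = optimize.minimize(
        objective,
        z0,
        jac=grad,
        bounds=[(0.0, 1.0)] * (n + 1),
        constraints=[constraints],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    z = np.clip(res.x, 0.0, 1.0)

    def rel_residual(zv: np.ndarray) -> float:
        r = (B_full @ zv - d_full).reshape(-1, 3)
        scale = np.maximum(1.0, np.linalg.norm(problem.demand, axis=1))
        return float(np.max(np.linalg.norm(r, axis=1) / scale))

    if not res.success or rel_residual(z) > residual_tol:
        lc = optimize.LinearConstraint(B, d, d)
        res2 = optimize.minimize(
            objective,
            z0,
            jac=grad,
            bounds=optimize.Bounds(np.zeros(n + 1), np.ones(n + 1)),
            constraints=[lc],
            method="trust-constr",
            options={"maxiter": 2000, "xtol": 1e-12, "gtol": 1e-10},
        )
        z2 = np.clip(res2.x, 0.0, 1.0)
        if rel_residual(z2) < rel_residual(z) or (
            rel_residual(z2) <= residual_tol and objective(z2) <= objective(z)
        ):
            z, res = z2, res2
        if rel_residual(z) > residual_tol:
            raise RuntimeError(
                f"recruitment solver did not converge: relative residual "
                f"{rel_residual(z):.2e} after {getattr(res, 'nit', '?')} iterations"
            )

    activities = z[:n]
    forces = activities * problem.strengths
    residuals = (B_full @ z - d_full).reshape(-1, 3)
    return RecruitmentSolution(
        forces=forces,
        activities=activities,
        iap_kpa=float(z[n] * problem.iap_max_kpa),
        residuals=residuals,
        residual_rel=rel_residual(z),
        objective=float(np.sum(activities**3)),
        fascicle_names=problem.fascicle_names,
    )


def l5s1_loads(solution: RecruitmentSolution, posed: PosedModel) -> JointLoads:
    """Decompose the L5-S1 reaction into compression and shear.

    The reaction balances gravity of the superincumbent body, hand loads,
    muscle forces crossing the joint and the IAP thrust; components are taken
    in the S1 superior-endplate frame (pelvis frame plus the configured
    sacral tilt).
    """
    from .model import _superior_masses  # internal helper, same conventions

    chain = posed.chain
    f_total = np.zeros(3)
    for mass, _com in _superior_masses(posed, "L5S1"):
        f_total += mass * posed.gravity
    for load in posed.hand_loads:
        for mass, _pos in load.point_masses():
            f_total += mass * posed.gravity
    vectors = fascicle_force_vectors(posed, solution.forces)
    for k, fas in enumerate(chain.fascicles):
        if fas.crosses_joint(0):
            f_total += vectors[k]
    f_total += (
        solution.iap_kpa * 1000.0 * chain.iap.effective_area_m2 * posed.iap_axis
    )

    tilt = chain.geometry.get("sacral_tilt_deg", 0.0)
    from .kinematics import euler_to_matrix

    s1_frame = posed.frames["pelvis"] @ euler_to_matrix(np.array([tilt, 0.0, 0.0]))
    local = s1_frame.T @ f_total
    return JointLoads(
        compression=float(-local[2]),
        ap_shear=float(-local[0]),
        ml_shear=float(-local[1]),
        body_mass=chain.subject.mass,
    )


def normalize_bw(force_n: float, body_mass: float) -> float:
    """Express a force as percent of body weight."""
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    return 100.0 * force_n / (body_mass * GRAVITY)
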