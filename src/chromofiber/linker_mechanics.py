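"""Linker DNA mechanics at the base-pair step level.

DNA is represented as a chain of rigid base-pair frames; consecutive frames
are related by six step parameters (Twist, Roll, Tilt, Shift, Slide, Rise)
under the mid-step-triad convention used by CompDNA/3DNA.  The elastic
energy of a chain is a harmonic (quadratic) function of the deviations of
the step parameters from the B-DNA rest state (Twist = 34.5 deg,
Rise = 3.35 A, all else zero), with a 6x6 stiffness matrix averaged over
the 16 dinucleotides.

The central operation is :func:`optimize_linker`: find the minimum-energy
conformation of an L-bp linker whose two boundary frames (the exit frame of
one nucleosome and the entry frame of the next) are fixed.  Because the
boundary condition only fixes the *orientation* of the final frame and not
the number of helical turns accumulated along the way, the problem has
several locally optimal solutions ("twist topoisomers") whose total twist
differs by multiples of 360 degrees; each is optimized separately and all
are returned ranked by energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REST_TWIST",
    "REST_RISE",
    "BpStep",
    "RestState",
    "StiffnessModel",
    "LinkerConformation",
    "LinkerSolver",
    "reconstruct_frames",
    "extract_steps",
    "elastic_energy",
    "optimize_linker",
]

REST_TWIST = 34.5  # degrees per step, relaxed B-DNA
REST_RISE = 3.35  # Angstrom per step

#: rest-state vector in parameter order (twist, roll, tilt, shift, slide, rise)
REST_VECTOR = np.array([REST_TWIST, 0.0, 0.0, 0.0, 0.0, REST_RISE])

PARAM_NAMES = ("twist", "roll", "tilt", "shift", "slide", "rise")


@dataclass(frozen=True)
class BpStep:
    """One base-pair step: three angles (degrees) and three displacements (A)."""

    twist: float
    roll: float = 0.0
    tilt: float = 0.0
    shift: float = 0.0
    slide: float = 0.0
    rise: float = REST_RISE

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.twist, self.roll, self.tilt, self.shift, self.slide, self.rise]
        )

    @staticmethod
    def rest() -> "BpStep":
        return BpStep(twist=REST_TWIST, rise=REST_RISE)


@dataclass(frozen=True)
class RestState:
    """Relaxed B-DNA step parameters (fixed constants)."""

    twist: float = REST_TWIST
    rise: float = REST_RISE

    def as_array(self) -> np.ndarray:
        return np.array([self.twist, 0.0, 0.0, 0.0, 0.0, self.rise])


# Dinucleotide-averaged harmonic force constants, in kT per deg^2 / kT per A^2,
# parameter order (twist, roll, tilt, shift, slide, rise).  Diagonal values and
# the twist-roll coupling follow the commonly used knowledge-based averages for
# B-DNA; the full matrix can be replaced through the run configuration.
DEFAULT_DIAGONAL = np.array([0.0427, 0.0204, 0.0370, 1.72, 2.27, 7.04])
DEFAULT_TWIST_ROLL = 0.012


def _default_matrix() -> np.ndarray:
    f = np.diag(DEFAULT_DIAGONAL)
    f[0, 1] = f[1, 0] = DEFAULT_TWIST_ROLL
    return f


@dataclass(frozen=True)
class StiffnessModel:
    """Symmetric positive-definite 6x6 stiffness matrix for one bp step."""

    matrix: np.ndarray = field(default_factory=_default_matrix)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (6, 6):
            raise ValueError("stiffness matrix must be 6x6")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("stiffness matrix must be symmetric")
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError("stiffness matrix must be positive definite")
        object.__setattr__(self, "matrix", m)


@dataclass
class LinkerConformation:
    """An optimized linker: step parameters, frames, energy and topology tag.

    ``steps`` has shape (L+1, 6): the L+1 steps spanning exit bp -> L linker
    bp -> entry bp.  ``frames_R``/``frames_o`` hold the L+2 bp frames
    including both boundary frames.  ``twist_offset`` records which twist
    topoisomer branch (total imposed excess twist, degrees) the solution
    belongs to.
    """

    steps: np.ndarray
    frames_R: np.ndarray
    frames_o: np.ndarray
    elastic_energy: float
    twist_offset: float
    residual: float
    converged: bool


# ---------------------------------------------------------------------------
# rotation helpers (vectorized Rodrigues formulas)
# ---------------------------------------------------------------------------


def _rot(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotation matrices about unit ``axis`` (..., 3) by ``angle`` (...) rad."""
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    c = np.cos(angle)[..., None, None]
    s = np.sin(angle)[..., None, None]
    x, y, z = axis[..., 0], axis[..., 1], axis[..., 2]
    zero = np.zeros_like(x)
    k = np.stack(
        [
            np.stack([zero, -z, y], axis=-1),
            np.stack([z, zero, -x], axis=-1),
            np.stack([-y, x, zero], axis=-1),
        ],
        axis=-2,
    )
    eye = np.broadcast_to(np.eye(3), k.shape)
    return eye + s * k + (1.0 - c) * (k @ k)


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n = np.where(n < 1e-15, 1.0, n)
    return v / n


# ---------------------------------------------------------------------------
# step <-> frame conversion (mid-step triad convention)
# ---------------------------------------------------------------------------


def step_transform(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative transform of one (or many) steps in start-frame coordinates.

    Returns (R_rel, d_local) with shapes (..., 3, 3) and (..., 3) such that
    ``R2 = R1 @ R_rel`` and ``o2 = o1 + R1 @ d_local``.
    """
    p = np.asarray(params, dtype=float)
    tw, roll, tilt = np.deg2rad(p[..., 0]), np.deg2rad(p[..., 1]), np.deg2rad(p[..., 2])
    disp = p[..., 3:6]
    gamma = np.hypot(roll, tilt)
    phi = np.arctan2(tilt, roll)
    alpha = tw / 2.0 + phi
    # hinge axis in start-frame coordinates: y rotated by alpha about z
    hinge = np.stack([-np.sin(alpha), np.cos(alpha), np.zeros_like(alpha)], axis=-1)
    rh = _rot(hinge, gamma / 2.0)
    zm = rh[..., :, 2]  # rh @ z_hat
    r_rel = rh @ _rot(zm, tw) @ rh
    # mid-frame in start coordinates
    x1p = rh[..., :, 0]
    xm = (_rot(zm, tw / 2.0) @ x1p[..., None])[..., 0]
    ym = np.cross(zm, xm)
    rm = np.stack([xm, ym, zm], axis=-1)
    d_local = (rm @ disp[..., None])[..., 0]
    return r_rel, d_local


def reconstruct_frames(
    start_R: np.ndarray, start_o: np.ndarray, steps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Chain frames from a start frame and (M, 6) step parameters.

    Frame i+1 is obtained from frame i by the mid-step-triad convention: the
    bending rotation is split symmetrically about the mid frame and the
    displacement is applied in mid-frame coordinates.  Returns (M+1, 3, 3)
    rotation matrices (columns = X, Y, Z axes) and (M+1, 3) origins.
    """
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    m = steps.shape[0]
    r_rel, d_local = step_transform(steps)
    R = np.empty((m + 1, 3, 3))
    o = np.empty((m + 1, 3))
    R[0] = start_R
    o[0] = start_o
    for i in range(m):
        o[i + 1] = o[i] + R[i] @ d_local[i]
        R[i + 1] = R[i] @ r_rel[i]
    return R, o


def extract_steps(frames_R: np.ndarray, frames_o: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reconstruct_frames` under the same convention.

    Takes (M+1, 3, 3) frames and (M+1, 3) origins, returns (M, 6) step
    parameters in degrees / Angstrom.
    """
    R = np.asarray(frames_R, dtype=float)
    o = np.asarray(frames_o, dtype=float)
    if R.shape[0] < 2:
        raise ValueError("need at least two frames")
    if np.any(np.linalg.norm(np.diff(o, axis=0), axis=-1) < 1e-9):
        raise ValueError("coincident frame origins: degenerate geometry")
    R1, R2 = R[:-1], R[1:]
    o1, o2 = o[:-1], o[1:]
    z1, z2 = R1[..., :, 2], R2[..., :, 2]
    cosg = np.clip(np.sum(z1 * z2, axis=-1), -1.0, 1.0)
    gamma = np.arccos(cosg)
    hinge = np.cross(z1, z2)
    hn = np.linalg.norm(hinge, axis=-1, keepdims=True)
    # gamma == 0: hinge arbitrary (rotation by 0); use x1 to stay defined
    hinge = np.where(hn < 1e-12, R1[..., :, 0], hinge / np.where(hn < 1e-12, 1.0, hn))
    r_half_p = _rot(hinge, gamma / 2.0)
    r_half_m = _rot(hinge, -gamma / 2.0)
    R1p = r_half_p @ R1
    R2p = r_half_m @ R2
    zm = R1p[..., :, 2]
    x1p, x2p = R1p[..., :, 0], R2p[..., :, 0]
    tw = np.arctan2(
        np.sum(np.cross(x1p, x2p) * zm, axis=-1), np.sum(x1p * x2p, axis=-1)
    )
    xm = (_rot(zm, tw / 2.0) @ x1p[..., None])[..., 0]
    ym = np.cross(zm, xm)
    phi = np.arctan2(
        np.sum(np.cross(ym, hinge) * zm, axis=-1), np.sum(ym * hinge, axis=-1)
    )
    roll = gamma * np.cos(phi)
    tilt = gamma * np.sin(phi)
    rm = np.stack([xm, ym, zm], axis=-1)
    disp = (np.swapaxes(rm, -1, -2) @ (o2 - o1)[..., None])[..., 0]
    out = np.empty((R1.shape[0], 6))
    out[:, 0] = np.rad2deg(tw)
    out[:, 1] = np.rad2deg(roll)
    out[:, 2] = np.rad2deg(tilt)
    out[:, 3:6] = disp
    return out


# ---------------------------------------------------------------------------
# elastic energy
# ---------------------------------------------------------------------------


def elastic_energy(steps: np.ndarray, stiffness: StiffnessModel | None = None) -> float:
    """Harmonic deformation energy of a step chain, in kT.

    E = sum over steps of 1/2 * delta^T F delta with delta the deviation from
    the rest state.  Zero iff every step is at rest.
    """
    if stiffness is None:
        stiffness = StiffnessModel()
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    delta = steps - REST_VECTOR
    return float(0.5 * np.einsum("ij,jk,ik->", delta, stiffness.matrix, delta))


# ---------------------------------------------------------------------------
# boundary-constrained linker optimization
# ---------------------------------------------------------------------------


def _rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    """Rotation log map (axis*angle); hand-rolled to avoid per-call overhead."""
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(tr)
    if theta < 1e-8:
        return 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if theta > np.pi - 1e-6:
        # near-180 degrees: extract the axis from the symmetric part
        B = 0.5 * (R + np.eye(3))
        axis = np.sqrt(np.clip(np.diag(B), 0.0, None))
        # fix signs from the off-diagonal terms
        i = int(np.argmax(axis))
        if axis[i] > 0:
            axis = B[i] / axis[i]
            axis[i] = np.sqrt(np.clip(B[i, i], 0.0, None))
        n = np.linalg.norm(axis)
        axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
        sg = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        if sg @ axis < 0:
            axis = -axis
        return axis * theta
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return v * (theta / (2.0 * np.sin(theta)))


def _pose_error(
    R_end: np.ndarray, o_end: np.ndarray, R_tgt: np.ndarray, o_tgt: np.ndarray
) -> np.ndarray:
    """6-vector pose mismatch: rotation log (rad) then position error (A)."""
    rv = _rotvec_from_matrix(R_end.T @ R_tgt)
    return np.concatenate([rv, R_end.T @ (o_tgt - o_end)])


def _chain_poses(steps: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Relative transforms plus prefix rotation/origin arrays of a chain."""
    r_rel, d_local = step_transform(steps)
    n = steps.shape[0]
    R = np.empty((n + 1, 3, 3))
    o = np.empty((n + 1, 3))
    R[0] = np.eye(3)
    o[0] = 0.0
    for i in range(n):
        o[i + 1] = o[i] + R[i] @ d_local[i]
        R[i + 1] = R[i] @ r_rel[i]
    return r_rel, d_local, R, o


def _end_pose(steps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, _, R, o = _chain_poses(steps)
    return R[-1], o[-1]


_FD_EPS = np.array([1e-5, 1e-5, 1e-5, 1e-6, 1e-6, 1e-6])


def _chain_jacobian(steps: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """End-pose error Jacobian of a step chain (Gauss-Newton quality).

    Returns (J, R_end, o_end) where J is 6 x 6n: the derivative of the pose
    error 6-vector with respect to every step parameter.  Built from the
    right-perturbation identity  G -> G * exp(Ad_{S^-1} xi)  with S the
    suffix transform after the perturbed step, and the local step twist xi
    obtained by finite differences of the single-step transform (vectorized
    over all steps and parameters).
    """
    n = steps.shape[0]
    r_rel, d_local, R, o = _chain_poses(steps)

    # batch of perturbed single-step transforms: shape (n, 6) base -> (n, 6, 6)
    pert = steps[:, None, :] + np.eye(6)[None, :, :] * _FD_EPS[None, :, None]
    r_p, d_p = step_transform(pert.reshape(-1, 6))
    r_p = r_p.reshape(n, 6, 3, 3)
    d_p = d_p.reshape(n, 6, 3)

    # local twist xi = vee(T^-1 dT)/eps in the step's start frame
    rT = np.swapaxes(r_rel, -1, -2)
    dR = rT[:, None] @ (r_p - r_rel[:, None])  # (n, 6, 3, 3) skew to 1st order
    omega = np.stack(
        [
            dR[..., 2, 1] - dR[..., 1, 2],
            dR[..., 0, 2] - dR[..., 2, 0],
            dR[..., 1, 0] - dR[..., 0, 1],
        ],
        axis=-1,
    ) * 0.5
    v = (rT[:, None] @ (d_p - d_local[:, None])[..., None])[..., 0]
    omega /= _FD_EPS[None, :, None]
    v /= _FD_EPS[None, :, None]

    # suffix transforms S_i = T_{i+1} ... T_n expressed via prefix poses:
    # S_i = G_i^-1 G_n with G_i = (R[i+1], o[i+1]) after step i... we need the
    # transform carrying the perturbation at step i to the chain end:
    # G = P_{i-1} T_i S, S = T_{i+1}..T_n, so S = (P_i)^-1 G_end where
    # P_i = (R[i+1], o[i+1]).
    R_end, o_end = R[-1], o[-1]
    Rs = np.swapaxes(R[1:], -1, -2) @ R_end  # S rotation for each step i
    ts = (np.swapaxes(R[1:], -1, -2) @ (o_end - o[1:])[..., None])[..., 0]

    # Ad_{S^-1}: omega' = Rs^T omega ; v' = Rs^T v - (Rs^T ts_term) ...
    RsT = np.swapaxes(Rs, -1, -2)
    om2 = (RsT[:, None] @ omega[..., None])[..., 0]
    t_inv = -(RsT @ ts[..., None])[..., 0]  # translation of S^-1
    v2 = np.cross(np.broadcast_to(t_inv[:, None], om2.shape), om2) + (
        RsT[:, None] @ v[..., None]
    )[..., 0]

    # pose error derivative wrt right perturbation is -identity to first order
    J = -np.concatenate([om2, v2], axis=-1)  # (n, 6 params, 6 error comps)
    J = np.transpose(J, (2, 0, 1)).reshape(6, 6 * n)
    return J, R_end, o_end


def _sqp_solve(
    x0: np.ndarray,
    r_tgt: np.ndarray,
    o_tgt: np.ndarray,
    Finv_block: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 25,
) -> tuple[np.ndarray, float, bool]:
    """Constrained minimization of the harmonic chain energy by SQP.

    The energy is exactly quadratic, so each iteration solves the KKT system
    of the problem with the end-pose constraint linearized at the current
    chain; a backtracking line search on the constraint norm keeps the
    iteration stable.
    """
    n = x0.shape[0]
    x = x0.copy()
    J, R_end, o_end = _chain_jacobian(x)
    err = _pose_error(R_end, o_end, r_tgt, o_tgt)
    for _ in range(max_iter):
        nrm = float(np.linalg.norm(err))
        if nrm < tol:
            return x, nrm, True
        delta0 = (x - REST_VECTOR).ravel()
        Hinv_Jt = Finv_block @ J.T
        S = J @ Hinv_Jt + 1e-12 * np.eye(6)
        lam = np.linalg.solve(S, -err + J @ delta0)
        d = (-delta0 + Hinv_Jt @ lam).reshape(n, 6)
        scale = 1.0
        x_new, err_new = x, err
        for _ in range(10):
            x_try = x + scale * d
            R_e, o_e = _end_pose(x_try)
            err_try = _pose_error(R_e, o_e, r_tgt, o_tgt)
            if np.linalg.norm(err_try) <= max(0.9 * nrm, 0.5 * tol):
                x_new, err_new = x_try, err_try
                break
            scale *= 0.5
        else:
            # no progress possible along this direction
            return x, nrm, nrm < 10 * tol
        x, err = x_new, err_new
        J, _, _ = _chain_jacobian(x)
    nrm = float(np.linalg.norm(err))
    return x, nrm, nrm < tol


def _penalty_minimize(
    x0: np.ndarray,
    r_tgt: np.ndarray,
    o_tgt: np.ndarray,
    F: np.ndarray,
    weights: tuple[float, ...] = (10.0, 1e3, 1e4),
) -> np.ndarray:
    """Quadratic-penalty relaxation of the end-pose constraint.

    Minimizes E(x) + w/2 * ||pose error||^2 with an escalating weight w
    (rotation errors in rad are scaled to match position errors in A),
    using L-BFGS with the analytic chain Jacobian.  Robust far from the
    constraint manifold; the result is then projected by SQP.
    """
    from scipy.optimize import minimize

    n = x0.shape[0]
    err_scale = np.array([20.0, 20.0, 20.0, 1.0, 1.0, 1.0])  # rad -> ~A

    state = {"w": weights[0]}

    def fun(xflat):
        x = xflat.reshape(n, 6)
        J, R_end, o_end = _chain_jacobian(x)
        err = _pose_error(R_end, o_end, r_tgt, o_tgt) * err_scale
        delta = x - REST_VECTOR
        e_el = 0.5 * np.einsum("ij,jk,ik->", delta, F, delta)
        val = e_el + 0.5 * state["w"] * err @ err
        grad = (delta @ F).ravel() + state["w"] * ((err * err_scale) @ J)
        return val, grad

    x = x0.ravel().copy()
    for w in weights:
        state["w"] = w
        res = minimize(fun, x, jac=True, method="L-BFGS-B", options={"maxiter": 100})
        x = res.x
    return x.reshape(n, 6)


def _slerp_pose(
    R0: np.ndarray, o0: np.ndarray, R1: np.ndarray, o1: np.ndarray, s: float
) -> tuple[np.ndarray, np.ndarray]:
    rv = _rotvec_from_matrix(R0.T @ R1)
    return R0 @ _rot(_normalize(rv) if np.linalg.norm(rv) > 0 else np.array([0.0, 0.0, 1.0]), s * np.linalg.norm(rv)), (1 - s) * o0 + s * o1


DEFAULT_TWIST_OFFSETS = (-720.0, -360.0, 0.0, 360.0, 720.0)


class LinkerSolver:
    """Boundary-value solver for an L-bp linker at fixed stiffness.

    Precomputes, for every twist topoisomer branch, a reference chain (rest
    state plus uniformly distributed excess twist), its end pose, the chain
    Jacobian there and the reduced 6x6 compliance form.  This gives a
    closed-form second-order estimate of the constrained minimum energy as a
    quadratic function of the 6-D pose mismatch — the workhorse of landscape
    scans — while :meth:`solve` runs the exact SQP with continuation.
    """

    def __init__(
        self,
        L: int,
        stiffness: StiffnessModel | None = None,
        twist_offsets: tuple[float, ...] = DEFAULT_TWIST_OFFSETS,
    ):
        if L < 1:
            raise ValueError("linker length must be >= 1 bp")
        self.L = int(L)
        self.n = self.L + 1
        self.stiffness = stiffness if stiffness is not None else StiffnessModel()
        self.twist_offsets = tuple(float(t) for t in twist_offsets)
        Finv = np.linalg.inv(self.stiffness.matrix)
        self.Finv_block = np.kron(np.eye(self.n), Finv)
        self._branches = {}
        for off in self.twist_offsets:
            steps = np.tile(REST_VECTOR, (self.n, 1))
            steps[:, 0] += off / self.n
            J, R_end, o_end = _chain_jacobian(steps)
            M = np.linalg.inv(J @ self.Finv_block @ J.T + 1e-12 * np.eye(6))
            w = J @ (steps - REST_VECTOR).ravel()
            self._branches[off] = {
                "steps": steps,
                "R_end": R_end,
                "o_end": o_end,
                "J": J,
                "M": M,
                "w": w,
            }

    # -- fast path -------------------------------------------------------

    def approx_energy(self, r_rel: np.ndarray, d_rel: np.ndarray) -> tuple[float, float]:
        """Second-order estimate of min energy over branches: (E, branch)."""
        best = (np.inf, 0.0)
        for off, b in self._branches.items():
            err = _pose_error(b["R_end"], b["o_end"], r_rel, d_rel)
            u = b["w"] - err
            e_val = 0.5 * float(u @ b["M"] @ u)
            if e_val < best[0]:
                best = (e_val, off)
        return best

    # -- exact path ------------------------------------------------------

    def solve(
        self,
        r_rel: np.ndarray,
        d_rel: np.ndarray,
        branches: tuple[float, ...] | None = None,
    ) -> list[LinkerConformation]:
        """Exact constrained optimization for each topoisomer branch."""
        # a B-DNA chain cannot extend much beyond its contour length; refuse
        # plainly unreachable boundaries instead of burning SQP iterations
        if np.linalg.norm(d_rel) > 4.5 * self.n:
            raise ValueError(
                f"boundary separation {np.linalg.norm(d_rel):.0f} A exceeds the "
                f"reach of a {self.L}-bp linker"
            )
        out: list[LinkerConformation] = []
        for off in branches if branches is not None else self.twist_offsets:
            b = self._branches[float(off)]
            x = b["steps"].copy()
            R_ref, o_ref = b["R_end"], b["o_end"]
            # direct SQP first (fast when the basin is benign), then the
            # escalating quadratic-penalty relaxation followed by SQP
            # projection onto the exact constraint
            target_twist = self.n * REST_TWIST + off

            def in_class(xx):
                return abs(float(xx[:, 0].sum()) - target_twist) < 180.0

            x, res, ok = _sqp_solve(x, r_rel, d_rel, self.Finv_block)
            if not ok or not in_class(x):
                x2 = _penalty_minimize(b["steps"].copy(), r_rel, d_rel, self.stiffness.matrix)
                x2, res2, ok2 = _sqp_solve(x2, r_rel, d_rel, self.Finv_block)
                if ok2 and (in_class(x2) or not ok):
                    x, res, ok = x2, res2, ok2
            if not ok or not in_class(x):
                # pose continuation preserves the twist class best
                x3 = b["steps"].copy()
                ok3 = False
                for s in np.linspace(0.1, 1.0, 10):
                    R_s, o_s = _slerp_pose(R_ref, o_ref, r_rel, d_rel, s)
                    x3, res3, ok3 = _sqp_solve(x3, R_s, o_s, self.Finv_block)
                if ok3 and (in_class(x3) or not ok):
                    x, res, ok = x3, res3, ok3
            frames_R, frames_o = reconstruct_frames(np.eye(3), np.zeros(3), x)
            out.append(
                LinkerConformation(
                    steps=x,
                    frames_R=frames_R,
                    frames_o=frames_o,
                    elastic_energy=elastic_energy(x, self.stiffness),
                    twist_offset=off,
                    residual=res,
                    converged=ok,
                )
            )
        out.sort(key=lambda c: (not c.converged, c.elastic_energy))
        # drop duplicates: branches that relaxed into an already-found basin
        dedup: list[LinkerConformation] = []
        for c in out:
            if not any(
                np.allclose(c.steps, d.steps, atol=1e-4) for d in dedup
            ):
                dedup.append(c)
        return dedup


def optimize_linker(
    exit_R: np.ndarray,
    exit_o: np.ndarray,
    entry_R: np.ndarray,
    entry_o: np.ndarray,
    L: int,
    stiffness: StiffnessModel | None = None,
    twist_offsets: tuple[float, ...] = DEFAULT_TWIST_OFFSETS,
) -> list[LinkerConformation]:
    """Minimum-energy linker conformations between two fixed boundary frames.

    The L+1 steps span exit bp -> L linker bp -> entry bp.  For each twist
    topoisomer branch (imposed excess twist in ``twist_offsets``, relative to
    the relaxed-twist solution) the chain is optimized by SQP under the exact
    end-frame constraint (tolerance well below 1e-3 A / 1e-3 rad); distinct
    twist topoisomers are optimized independently so that none silently
    collapses onto another.  Solutions are returned sorted by elastic energy,
    with frames expressed in the global coordinates of the boundary frames.
    """
    exit_R = np.asarray(exit_R, dtype=float)
    entry_R = np.asarray(entry_R, dtype=float)
    exit_o = np.asarray(exit_o, dtype=float)
    entry_o = np.asarray(entry_o, dtype=float)
    if np.linalg.norm(entry_o - exit_o) < 1e-9 and np.allclose(exit_R, entry_R):
        raise ValueError("boundary frames coincide")
    solver = LinkerSolver(L, stiffness, twist_offsets)
    r_rel = exit_R.T @ entry_R
    d_rel = exit_R.T @ (entry_o - exit_o)
    results = solver.solve(r_rel, d_rel)
    if not any(c.converged for c in results):
        best = min((c.residual for c in results), default=np.inf)
        raise RuntimeError(
            f"linker optimization did not reach the boundary frame (best residual {best:.3g})"
        )
    # re-express frames in global coordinates
    for c in results:
        c.frames_o = (exit_R @ c.frames_o[..., None])[..., 0] + exit_o
        c.frames_R = exit_R @ c.frames_R
    return results
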