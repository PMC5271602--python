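"""Rigid nucleosome core model and regular-fiber placement.

The nucleosome core is treated as a rigid body: 147 base-pair frames on a
left-handed superhelix around the core's superhelical axis (local Z), with
the dyad axis (local X) through the central base pair.  A regular symmetric
fiber places N copies of the core on a helix described by four parameters:
radius r, rise h, polar angle phi (all cylindrical, about the global fiber
axis) and the inclination angle rho, a rotation of each core about its own
dyad axis.  One rigid screw motion (rotation phi about the fiber axis plus
translation h along it) maps nucleosome k onto nucleosome k+1 for every k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linker_mechanics import REST_TWIST, _normalize, _rot, extract_steps

__all__ = [
    "Frame",
    "NucleosomeCore",
    "FiberParams",
    "make_ideal_core",
    "load_core_from_pdb",
    "place_nucleosomes",
    "compose_frames",
]

#: canonical nucleosome core dimensions (crystal-structure values)
CORE_BP = 147
SUPERHELIX_RADIUS = 41.9  # A
SUPERHELIX_PITCH = 25.9  # A per superhelical turn
SUPERHELIX_TURNS = 1.67
DISK_RADIUS = 55.0  # steric envelope, A
DISK_HEIGHT = 57.0  # steric envelope, A


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal coordinate frame: origin (A) and axis matrix.

    ``axes`` columns are the X, Y, Z unit vectors in parent coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        a = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(a.T @ a, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(a) < 0:
            raise ValueError("frame must be right-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", a)

    @staticmethod
    def identity() -> "Frame":
        return Frame(np.zeros(3), np.eye(3))

    @staticmethod
    def _unchecked(origin: np.ndarray, axes: np.ndarray) -> "Frame":
        """Internal fast constructor for axes known orthonormal by construction."""
        f = object.__new__(Frame)
        object.__setattr__(f, "origin", origin)
        object.__setattr__(f, "axes", axes)
        return f


def compose_frames(outer: Frame, R: np.ndarray, o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Express local frames (R (...,3,3), o (...,3)) in the outer frame."""
    return outer.axes @ R, (outer.axes @ np.asarray(o)[..., None])[..., 0] + outer.origin


@dataclass
class NucleosomeCore:
    """Rigid 147-bp nucleosome core in its own (core-frame) coordinates.

    The core frame is the identity: local Z is the nucleosome superhelical
    axis, local X the dyad axis through the central base pair.  ``bp_R`` /
    ``bp_o`` hold the 147 base-pair frames (5'->3' of the top strand);
    ``anchor_in`` / ``anchor_out`` mark the two flat faces used by the
    stacking term, at the disk center -/+ height/2 along Z.
    """

    bp_R: np.ndarray
    bp_o: np.ndarray
    radius_disk: float = DISK_RADIUS
    height_disk: float = DISK_HEIGHT
    superhelix_fit_residual: float = 0.0

    def __post_init__(self):
        if self.bp_R.shape[0] != self.bp_o.shape[0]:
            raise ValueError("frame count mismatch")
        if self.bp_R.shape[0] != CORE_BP:
            raise ValueError(f"nucleosome core must have {CORE_BP} bp frames")

    @property
    def n_bp(self) -> int:
        return self.bp_o.shape[0]

    @property
    def entry_R(self) -> np.ndarray:
        return self.bp_R[0]

    @property
    def entry_o(self) -> np.ndarray:
        return self.bp_o[0]

    @property
    def exit_R(self) -> np.ndarray:
        return self.bp_R[-1]

    @property
    def exit_o(self) -> np.ndarray:
        return self.bp_o[-1]

    @property
    def anchor_in(self) -> np.ndarray:
        return np.array([0.0, 0.0, -0.5 * self.height_disk])

    @property
    def anchor_out(self) -> np.ndarray:
        return np.array([0.0, 0.0, 0.5 * self.height_disk])

    def twist_profile(self) -> np.ndarray:
        """Extracted per-step twist (degrees) along the core DNA."""
        return extract_steps(self.bp_R, self.bp_o)[:, 0]


@dataclass(frozen=True)
class FiberParams:
    """Four superhelical fiber parameters plus linker length and fiber size.

    r (A) and h (A) are the cylindrical radius and per-nucleosome rise of
    the nucleosome centers about the fiber axis, phi (degrees) the polar
    angle between consecutive nucleosomes (left-handed two-start fibers
    have phi between 150 and 180 degrees), rho (degrees) the inclination of
    the nucleosome disk, i.e. its rotation about its own dyad axis.  L is
    the linker length in bp and N the number of nucleosomes.
    """

    r: float
    h: float
    phi: float
    rho: float
    L: int
    N: int = 2

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("fiber radius must be positive")
        if self.N < 1:
            raise ValueError("need at least one nucleosome")
        if not 1 <= self.L <= 100:
            raise ValueError("linker length out of supported range")

    @property
    def nrl(self) -> int:
        """Nucleosome repeat length, bp (147-bp core + linker)."""
        return CORE_BP + self.L


def _bishop_frames(origins: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangents plus a parallel-transported (twist-free) normal/binormal."""
    n = origins.shape[0]
    t = np.empty((n, 3))
    t[1:-1] = origins[2:] - origins[:-2]
    t[0] = origins[1] - origins[0]
    t[-1] = origins[-1] - origins[-2]
    t = _normalize(t)
    normal = np.empty((n, 3))
    seed = np.array([0.0, 0.0, 1.0])
    if abs(seed @ t[0]) > 0.9:
        seed = np.array([1.0, 0.0, 0.0])
    normal[0] = _normalize(seed - (seed @ t[0]) * t[0])
    for i in range(1, n):
        v = normal[i - 1] - (normal[i - 1] @ t[i]) * t[i]
        normal[i] = _normalize(v)
    binormal = np.cross(t, normal)
    return t, normal, binormal


def _frames_with_twist(
    origins: np.ndarray, twist_rate_deg: float, phase_deg: float
) -> np.ndarray:
    t, nrm, bnr = _bishop_frames(origins)
    k = np.arange(origins.shape[0])
    psi = np.deg2rad(phase_deg + twist_rate_deg * k)
    x = np.cos(psi)[:, None] * nrm + np.sin(psi)[:, None] * bnr
    y = np.cross(t, x)
    return np.stack([x, y, t], axis=-1)


def make_ideal_core(
    n_bp: int = CORE_BP,
    sh_radius: float = SUPERHELIX_RADIUS,
    sh_pitch: float = SUPERHELIX_PITCH,
    n_turns: float = SUPERHELIX_TURNS,
) -> NucleosomeCore:
    """Idealized nucleosome core: bp frames on a left-handed superhelix.

    The DNA axis completes ``n_turns`` left-handed turns of the given radius
    and pitch about the core Z axis; base-pair frames are built by parallel
    transport with a uniform twist rate calibrated so the extracted per-step
    twist equals the B-DNA rest twist (34.5 degrees) — the rigid core then
    contributes no twist change relative to relaxed DNA.  The dyad axis X
    passes through the central base pair.
    """
    if sh_radius <= 0 or sh_pitch < 0 or n_turns <= 0 or n_bp < 2:
        raise ValueError("core geometry parameters must be positive")
    k = np.arange(n_bp, dtype=float)
    mid = (n_bp - 1) / 2.0
    dtheta = 2.0 * np.pi * n_turns / (n_bp - 1)
    # left-handed: azimuth decreases as z increases
    theta = -dtheta * (k - mid)
    z = sh_pitch * n_turns / (n_bp - 1) * (k - mid)
    origins = np.column_stack(
        [sh_radius * np.cos(theta), sh_radius * np.sin(theta), z]
    )

    # calibrate the applied twist rate so the CEHS-extracted twist is exactly
    # the rest twist (parallel-transport twist and extracted twist differ by a
    # small curvature correction)
    rate = REST_TWIST
    for _ in range(3):
        R = _frames_with_twist(origins, rate, 0.0)
        tw = extract_steps(R, origins)[:, 0].mean()
        rate += REST_TWIST - tw
    # phase so the dyad bp x-axis points radially outward (along core X)
    R = _frames_with_twist(origins, rate, 0.0)
    i_mid = int(mid)
    radial = _normalize(np.array([origins[i_mid, 0], origins[i_mid, 1], 0.0]))
    x_mid = R[i_mid, :, 0]
    y_mid = R[i_mid, :, 1]
    phase = np.rad2deg(np.arctan2(radial @ y_mid, radial @ x_mid))
    R = _frames_with_twist(origins, rate, phase)
    return NucleosomeCore(bp_R=R, bp_o=origins)


def place_nucleosomes(params: FiberParams) -> list[Frame]:
    """Frames of the N nucleosome cores of a regular symmetric fiber.

    Nucleosome k sits at cylindrical coordinates (r, k*phi, k*h) about the
    global fiber axis (Z).  Its orientation is the reference orientation --
    dyad axis X pointing radially inward (the DNA entry/exit sites, which
    flank the dyad, then face the fiber interior where the linkers run),
    superhelical axis Z along the fiber axis -- first rotated by the
    inclination rho about its own dyad axis, then carried around the fiber
    by the screw rotation k*phi.
    """
    rho = np.deg2rad(params.rho)
    phi = np.deg2rad(params.phi)
    base = np.diag([-1.0, -1.0, 1.0])  # dyad inward, right-handed
    R_incl = base @ _rot(np.array([1.0, 0.0, 0.0]), rho)
    k = np.arange(params.N)
    Rz = _rot(np.broadcast_to([0.0, 0.0, 1.0], (params.N, 3)), k * phi)
    axes = Rz @ R_incl
    origins = np.column_stack(
        [params.r * np.cos(k * phi), params.r * np.sin(k * phi), k * params.h]
    )
    return [Frame._unchecked(origins[i], axes[i]) for i in range(params.N)]


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

_DNA_RESNAMES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U"}


def _fit_helix_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares helix-axis fit to bp centers.

    Finds the axis direction and a point on it minimizing the variance of
    the radial distances of the points from the axis.  Returns (direction,
    point_on_axis, rms_residual_of_radius).  A nearly straight path makes
    the fit degenerate, signalled by a large residual-to-radius ratio.
    """
    from scipy.optimize import least_squares

    c0 = points.mean(axis=0)
    # initial direction: smallest-variance principal axis works for a flat
    # superhelix; for elongated paths use the largest axis as starting point
    u, s, vt = np.linalg.svd(points - c0)

    def radial(params):
        th, ph, px, py, pz = params
        d = np.array(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        p = np.array([px, py, pz])
        rel = points - p
        perp = rel - np.outer(rel @ d, d)
        r = np.linalg.norm(perp, axis=1)
        return r - r.mean()

    best = None
    for d0 in (vt[2], vt[0]):
        th0 = np.arccos(np.clip(d0[2], -1, 1))
        ph0 = np.arctan2(d0[1], d0[0])
        try:
            res = least_squares(radial, [th0, ph0, *c0], method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    th, ph, px, py, pz = best.x
    d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    p = np.array([px, py, pz])
    rel = points - p
    perp = rel - np.outer(rel @ d, d)
    radii = np.linalg.norm(perp, axis=1)
    rms = float(np.sqrt(np.mean((radii - radii.mean()) ** 2)))
    return d, p, rms


def load_core_from_pdb(path, degenerate_threshold: float = 5.0) -> NucleosomeCore:
    """Build a nucleosome core from a PDB file with two paired DNA chains.

    Base pairs are formed between residue i of the longer strand and residue
    n-1-i of its complement; the bp frame origin is the C1'-C1' midpoint,
    with Z along the local chain direction and Y along the paired C1'-C1'
    vector.  The superhelical axis is fitted to the bp centers by least
    squares and the core is re-expressed in its own frame (Z = fitted axis,
    X = dyad direction).  Raises a ``ValueError`` for missing or short DNA
    chains; a near-straight DNA path (degenerate axis fit) also raises, as
    no superhelical frame is then defined.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("core", str(path))
    model = next(structure.get_models())
    dna_chains = []
    for chain in model:
        res = [
            r
            for r in chain
            if r.get_resname().strip() in _DNA_RESNAMES and "C1'" in r
        ]
        if len(res) >= 10:
            dna_chains.append(res)
    if len(dna_chains) < 2:
        raise ValueError("PDB file must contain two DNA chains")
    dna_chains.sort(key=len, reverse=True)
    s1, s2 = dna_chains[0], dna_chains[1]
    n = min(len(s1), len(s2))
    if n < CORE_BP:
        raise ValueError(
            f"DNA chains too short for a nucleosome core: {n} < {CORE_BP} bp"
        )
    s1 = s1[:CORE_BP]
    s2 = s2[:CORE_BP]
    c1 = np.array([r["C1'"].get_coord() for r in s1], dtype=float)
    c2 = np.array([r["C1'"].get_coord() for r in s2], dtype=float)[::-1]
    origins = 0.5 * (c1 + c2)
    d_pair = np.linalg.norm(c1 - c2, axis=1)
    if np.any(d_pair > 15.0):
        raise ValueError("unpaired bases: C1'-C1' distance exceeds 15 A")

    # frames: Z along chain direction, Y toward strand-2 C1', X = Y x Z
    t, _, _ = _bishop_frames(origins)
    y = c2 - c1
    y = _normalize(y - np.sum(y * t, axis=1, keepdims=True) * t)
    x = np.cross(y, t)
    bp_R = np.stack([x, y, t], axis=-1)

    axis_d, axis_p, rms = _fit_helix_axis(origins)
    radii = np.linalg.norm(
        (origins - axis_p) - np.outer((origins - axis_p) @ axis_d, axis_d), axis=1
    )
    if rms > degenerate_threshold or radii.mean() < 5.0:
        raise ValueError(
            f"degenerate superhelix fit (residual {rms:.2f} A): "
            "DNA path is not superhelical"
        )
    # orient the axis along the chain's entry->exit progression
    if (origins[-1] - origins[0]) @ axis_d < 0:
        axis_d = -axis_d
    # core frame: Z = axis, X = dyad direction (axis -> central bp)
    i_mid = CORE_BP // 2
    center = axis_p + ((origins.mean(axis=0) - axis_p) @ axis_d) * axis_d
    xdir = origins[i_mid] - (axis_p + ((origins[i_mid] - axis_p) @ axis_d) * axis_d)
    xdir = _normalize(xdir)
    ydir = np.cross(axis_d, xdir)
    core_axes = np.column_stack([xdir, ydir, axis_d])
    # express bp frames in core coordinates
    bp_R_local = core_axes.T @ bp_R
    bp_o_local = (origins - center) @ core_axes
    return NucleosomeCore(
        bp_R=bp_R_local, bp_o=bp_o_local, superhelix_fit_residual=rms
    )
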