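"""Four-term energy of a regular two-start chromatin fiber.

The total energy per fiber is the sum of

* the elastic energy of the linker DNA (harmonic base-pair step potential,
  :mod:`~chromofiber.linker_mechanics`),
* electrostatic repulsion between DNA base-pair centers (Coulomb potential
  with a 30 A distance cutoff, one effective point charge per bp),
* steric repulsion between nucleosome envelopes and DNA segments
  (soft-core quadratic overlap penalty), and
* the phenomenological histone tail / acidic-patch stacking attraction
  between same-stack neighbors (k, k+2), a Gaussian well in the distance
  between the facing flat-face anchor points.

Because a regular fiber is generated by one screw motion, every pairwise
term between repeat units depends only on the unit separation d; energies
for any fiber size N are assembled from O(d_max) block interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linker_mechanics import LinkerConformation, StiffnessModel
from .nucleosome_geometry import FiberParams, Frame, NucleosomeCore, compose_frames, place_nucleosomes

__all__ = [
    "EnergyBreakdown",
    "ElectrostaticsModel",
    "StericModel",
    "StackingModel",
    "EnergyModels",
    "electrostatic_energy",
    "steric_energy",
    "stacking_energy",
    "total_energy",
    "FiberEnergyEvaluator",
]


@dataclass
class EnergyBreakdown:
    """Energy components of a fiber, in kT (reported per nucleosome)."""

    elastic: float
    electrostatic: float
    steric: float
    stacking: float

    @property
    def total(self) -> float:
        return self.elastic + self.electrostatic + self.steric + self.stacking

    def as_dict(self) -> dict:
        return {
            "elastic": self.elastic,
            "electrostatic": self.electrostatic,
            "steric": self.steric,
            "stacking": self.stacking,
            "total": self.total,
        }


@dataclass(frozen=True)
class ElectrostaticsModel:
    """Coulomb repulsion between effective bp point charges.

    ``scale`` is the prefactor q^2/eps_eff in kT*A: the pair energy is
    scale * (1/d - 1/cutoff) for d below the 30 A cutoff (shifted so the
    potential is continuous there) or scale/d when ``shifted`` is disabled.
    """

    scale: float = 0.5
    cutoff: float = 30.0
    charge: float = 1.0
    shifted: bool = True


@dataclass(frozen=True)
class StericModel:
    """Soft-core overlap penalties.

    The nucleosome envelope (a disk 55 A radius x 57 A height) is packed
    with nine spheres of radius ``env_sphere_radius``; DNA is a chain of
    10 A-radius beads at the bp centers.  Overlap depth x costs k*x^2,
    with the summed term capped.
    """

    k_env: float = 2.0  # kT/A^2, envelope-envelope sphere pairs
    k_dna: float = 0.5  # kT/A^2, DNA bead pairs and bead-octamer
    dna_radius: float = 10.0
    env_sphere_radius: float = 28.5
    octamer_radius: float = 30.0  # histone core sphere blocking DNA passage
    cap: float = 1e3
    min_chain_sep: int = 10  # bp separation below which DNA self-overlap is ignored


@dataclass(frozen=True)
class StackingModel:
    """Gaussian attraction between facing flat faces of stacked nucleosomes.

    ``d0`` is the rest distance between the face anchor points of a stacked
    (k, k+2) pair — 3 A face-to-face, i.e. 60 A center-to-center for
    coaxial disks; ``e0`` the well depth in kT.
    """

    e0: float = 8.0
    d0: float = 3.0
    sigma: float = 6.0


@dataclass(frozen=True)
class EnergyModels:
    stiffness: StiffnessModel = field(default_factory=StiffnessModel)
    electrostatics: ElectrostaticsModel = field(default_factory=ElectrostaticsModel)
    steric: StericModel = field(default_factory=StericModel)
    stacking: StackingModel = field(default_factory=StackingModel)


# ---------------------------------------------------------------------------
# standalone term operations
# ---------------------------------------------------------------------------


def electrostatic_energy(
    charges: np.ndarray,
    model: ElectrostaticsModel | None = None,
    chain_index: np.ndarray | None = None,
) -> float:
    """Pairwise Coulomb energy of point charges with a hard distance cutoff.

    ``chain_index`` assigns each site a position along the DNA chain; pairs
    closer than 2 bp along the chain (the same or adjacent base pairs) are
    excluded.  Overlapping sites (d < 0.1 A) raise a geometry error.
    """
    if model is None:
        model = ElectrostaticsModel()
    pts = np.asarray(charges, dtype=float)
    n = pts.shape[0]
    if n < 2:
        return 0.0
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    if chain_index is not None:
        ci = np.asarray(chain_index)
        sep = np.abs(ci[iu[0]] - ci[iu[1]])
        keep = sep >= 2
        dv = dv[keep]
    if np.any(dv < 0.1):
        raise ValueError("overlapping charge sites (d < 0.1 A)")
    mask = dv < model.cutoff
    dv = dv[mask]
    q2 = model.charge**2
    if model.shifted:
        return float(model.scale * q2 * np.sum(1.0 / dv - 1.0 / model.cutoff))
    return float(model.scale * q2 * np.sum(1.0 / dv))


def _sphere_overlap_energy(
    a: np.ndarray, ra: float, b: np.ndarray, rb: float, k: float, cap: float = 1e3
) -> float:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    touch = (ra + rb) ** 2
    close = d2 < touch
    if not np.any(close):
        return 0.0
    depth = ra + rb - np.sqrt(d2[close])
    return float(np.sum(np.minimum(k * depth**2, cap)))


def _envelope_spheres(core: NucleosomeCore, model: StericModel) -> np.ndarray:
    """Sphere-packed steric envelope of the nucleosome disk, core frame."""
    ring_r = core.radius_disk - model.env_sphere_radius + 2.0
    ang = np.linspace(0, 2 * np.pi, 9)[:-1]
    ring = np.column_stack(
        [ring_r * np.cos(ang), ring_r * np.sin(ang), np.zeros(8)]
    )
    return np.vstack([np.zeros(3), ring])


def steric_energy(
    env_centers: list[np.ndarray],
    dna_points: np.ndarray | None = None,
    dna_chain_index: np.ndarray | None = None,
    model: StericModel | None = None,
) -> float:
    """Soft-core steric energy of placed envelopes and DNA bead chains.

    ``env_centers`` is one (9, 3) sphere-center array per nucleosome.
    DNA beads closer than ``min_chain_sep`` along the chain are skipped
    (bonded neighbors are not sterically independent).
    """
    if model is None:
        model = StericModel()
    e = 0.0
    rs = model.env_sphere_radius
    for i in range(len(env_centers)):
        for j in range(i + 1, len(env_centers)):
            e += _sphere_overlap_energy(env_centers[i], rs, env_centers[j], rs, model.k_env)
    if dna_points is not None and len(dna_points):
        pts = np.asarray(dna_points, float)
        for env in env_centers:
            # DNA is blocked by the histone octamer at the disk center, not
            # by the full disk envelope (which the core DNA itself occupies)
            e += _sphere_overlap_energy(
                pts, model.dna_radius, env[:1], model.octamer_radius, model.k_dna
            )
        if dna_chain_index is not None:
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            ci = np.asarray(dna_chain_index)
            sep = np.abs(ci[:, None] - ci[None, :])
            iu = np.triu_indices(len(pts), k=1)
            keep = sep[iu] >= model.min_chain_sep
            depth = np.clip(2 * model.dna_radius - d[iu][keep], 0.0, None)
            e += float(np.sum(np.minimum(model.k_dna * depth**2, model.cap)))
    return e


def stacking_energy(
    anchors: list[tuple[np.ndarray, np.ndarray]],
    model: StackingModel | None = None,
) -> float:
    """Stacking attraction summed over same-stack neighbor pairs (k, k+2).

    ``anchors`` holds (anchor_in, anchor_out) global positions per
    nucleosome; the pair distance is the closest approach of the facing
    flat-face anchors.  Always non-positive; vanishes at large distance.
    """
    if model is None:
        model = StackingModel()
    e = 0.0
    for k in range(len(anchors) - 2):
        e += _stack_pair_energy(anchors[k], anchors[k + 2], model)
    return e


def _stack_pair_energy(anch_a, anch_b, model: StackingModel) -> float:
    d = min(
        np.linalg.norm(anch_a[0] - anch_b[1]),
        np.linalg.norm(anch_a[1] - anch_b[0]),
        np.linalg.norm(anch_a[0] - anch_b[0]),
        np.linalg.norm(anch_a[1] - anch_b[1]),
    )
    return -model.e0 * float(np.exp(-((d - model.d0) ** 2) / (2 * model.sigma**2)))


# ---------------------------------------------------------------------------
# assembled fiber energy with screw-block acceleration
# ---------------------------------------------------------------------------


class FiberEnergyEvaluator:
    """Evaluates the four-term fiber energy for a given core and models.

    One repeat unit (core + linker) is built in the frame of nucleosome 0;
    all pairwise terms between units separated by d screw steps are
    computed once per d and weighted by the pair multiplicity, so the cost
    is independent of N beyond the interaction range.
    """

    def __init__(self, core: NucleosomeCore, models: EnergyModels | None = None):
        self.core = core
        self.models = models if models is not None else EnergyModels()
        self._env_local = _envelope_spheres(core, self.models.steric)
        self._mask_cache: dict[int, dict] = {}

    def _masks(self, unit_len: int) -> dict:
        """Index masks that depend only on the repeat-unit layout."""
        if unit_len not in self._mask_cache:
            n_core = self.core.n_bp
            chain = np.arange(unit_len)
            is_core = chain < n_core
            iu = np.triu_indices(unit_len, k=1)
            sep = iu[1] - iu[0]
            both_core = is_core[iu[0]] & is_core[iu[1]]
            sep_c1 = np.abs(chain[:, None] - (chain[None, :] + unit_len))
            self._mask_cache[unit_len] = {
                "iu": iu,
                "keep_self_elec": (sep >= 2) & ~both_core,
                "keep_self_st": (sep >= self.models.steric.min_chain_sep) & ~both_core,
                "keep_c1": sep_c1 >= 2,
                "keep_dna1": sep_c1 >= self.models.steric.min_chain_sep,
                "is_core": is_core,
            }
        return self._mask_cache[unit_len]

    # -- geometry assembly ----------------------------------------------

    def _unit_geometry(self, params: FiberParams, linker: LinkerConformation):
        frames = place_nucleosomes(FiberParams(params.r, params.h, params.phi, params.rho, params.L, 2))
        f0 = frames[0]
        core_R, core_o = compose_frames(f0, self.core.bp_R, self.core.bp_o)
        pts = np.vstack([core_o, linker.frames_o[1:-1]])
        n_core = self.core.n_bp
        chain = np.arange(pts.shape[0])
        is_core = chain < n_core
        env = compose_frames(f0, np.eye(3), self._env_local)[1]
        anchors = (
            compose_frames(f0, np.eye(3), self.core.anchor_in[None, :])[1][0],
            compose_frames(f0, np.eye(3), self.core.anchor_out[None, :])[1][0],
        )
        screw_R = frames[1].axes @ f0.axes.T
        screw_t = frames[1].origin - screw_R @ f0.origin
        return pts, chain, is_core, env, anchors, (screw_R, screw_t)

    @staticmethod
    def _shift(pts: np.ndarray, screw, d: int, cache: dict) -> np.ndarray:
        if d not in cache:
            sR, st = screw
            R_acc, t_acc = np.eye(3), np.zeros(3)
            for _ in range(d):
                t_acc = sR @ t_acc + st
                R_acc = sR @ R_acc
            cache[d] = (R_acc, t_acc)
        R_acc, t_acc = cache[d]
        return (R_acc @ pts[..., None])[..., 0] + t_acc

    def evaluate(
        self,
        params: FiberParams,
        linker: LinkerConformation,
        N: int | None = None,
    ) -> EnergyBreakdown:
        """Per-nucleosome energy breakdown of the N-nucleosome fiber."""
        from ._kernels import HAVE_NUMBA, cross_block_sums, self_block_sums

        N = params.N if N is None else int(N)
        m = self.models
        pts, chain, is_core, env, anchors, screw = self._unit_geometry(params, linker)
        unit_len = pts.shape[0]
        cache: dict = {}
        use_kernel = HAVE_NUMBA and m.electrostatics.shifted

        # electrostatics ------------------------------------------------
        elec_models = m.electrostatics
        q2s = elec_models.scale * elec_models.charge**2
        # self term: within one unit, excluding intra-core pairs (the rigid
        # core's internal repulsion is a constant) and adjacent bp;
        # steric self: linker beads vs own envelope are excluded (the DNA
        # leaves the core within the envelope by construction); DNA-DNA
        # self pairs below min_chain_sep are bonded neighbors
        if use_kernel:
            c_self, s_self, dmin = self_block_sums(
                np.ascontiguousarray(pts),
                self.core.n_bp,
                elec_models.cutoff,
                2 * m.steric.dna_radius,
                m.steric.min_chain_sep,
                m.steric.k_dna,
                m.steric.cap,
            )
            if dmin < 0.1:
                raise ValueError("overlapping charge sites (d < 0.1 A)")
            e_elec_self = q2s * c_self
            e_st_self = s_self
        else:
            masks = self._masks(unit_len)
            iu = masks["iu"]
            dvec = np.linalg.norm(pts[iu[0]] - pts[iu[1]], axis=-1)
            e_elec_self = _coulomb_sum(dvec[masks["keep_self_elec"]], elec_models)
            depth = np.clip(
                2 * m.steric.dna_radius - dvec[masks["keep_self_st"]], 0.0, None
            )
            e_st_self = float(
                np.sum(np.minimum(m.steric.k_dna * depth**2, m.steric.cap))
            )

        # cross terms by unit separation --------------------------------
        # units 0..N-2 are full (core + linker), unit N-1 a bare core; at
        # separation d there are (N-1-d) full-full pairs and one
        # full-core pair (the last unit), all related by the screw motion
        e_elec_cross = 0.0
        e_st_cross = 0.0
        e_stack = 0.0
        r_bound = np.linalg.norm(pts - pts.mean(axis=0), axis=1).max() + 40.0
        n_core = self.core.n_bp
        rs = m.steric.env_sphere_radius
        lnk = pts[~is_core]
        for d in range(1, N):
            w_ff = max(N - 1 - d, 0)
            pts_d = self._shift(pts, screw, d, cache)
            center_gap = np.linalg.norm(pts_d.mean(axis=0) - pts.mean(axis=0))
            if center_gap > 2 * r_bound:
                break
            env_d = self._shift(env, screw, d, cache)
            lnk_d = pts_d[~is_core]

            # DNA cannot pass through the histone octamer (a 30 A sphere at
            # the disk center), but the linker of unit i may legitimately
            # approach nucleosome i+1 which it enters (d=1)
            oct0 = env[:1]
            oct_d = env_d[:1]
            r_oct = m.steric.octamer_radius

            if use_kernel:
                c_full, c_core, s_full, s_core, dmin = cross_block_sums(
                    np.ascontiguousarray(pts),
                    np.ascontiguousarray(pts_d),
                    d * unit_len,
                    n_core,
                    elec_models.cutoff,
                    2 * m.steric.dna_radius,
                    m.steric.min_chain_sep,
                    m.steric.k_dna,
                    m.steric.cap,
                )
                if dmin < 0.1:
                    raise ValueError("overlapping charge sites (d < 0.1 A)")
                el_full, el_core = q2s * c_full, q2s * c_core
                st_dna_full, st_dna_core = s_full, s_core
            else:
                masks = self._masks(unit_len)
                dd = np.linalg.norm(pts[:, None, :] - pts_d[None, :, :], axis=-1)
                if d == 1:
                    keep_c = masks["keep_c1"]
                    keep_dna = masks["keep_dna1"]
                    dd_el, dd_st = dd[keep_c], dd[keep_dna]
                    dd_cc_el = dd[:, :n_core][keep_c[:, :n_core]]
                    dd_cc_st = dd[:, :n_core][keep_dna[:, :n_core]]
                else:
                    dd_el = dd_st = dd
                    dd_cc_el = dd_cc_st = dd[:, :n_core]
                el_full = _coulomb_sum(dd_el, elec_models)
                el_core = _coulomb_sum(dd_cc_el, elec_models)
                depth = np.clip(2 * m.steric.dna_radius - dd_st, 0.0, None)
                st_dna_full = float(np.sum(np.minimum(m.steric.k_dna * depth**2, m.steric.cap)))
                depth = np.clip(2 * m.steric.dna_radius - dd_cc_st, 0.0, None)
                st_dna_core = float(np.sum(np.minimum(m.steric.k_dna * depth**2, m.steric.cap)))

            e_env = _sphere_overlap_energy(env, rs, env_d, rs, m.steric.k_env)
            e_lnk0_octd = (
                _sphere_overlap_energy(lnk, m.steric.dna_radius, oct_d, r_oct, m.steric.k_dna)
                if d != 1
                else 0.0
            )
            e_lnkd_oct0 = _sphere_overlap_energy(
                lnk_d, m.steric.dna_radius, oct0, r_oct, m.steric.k_dna
            )

            # full x full
            if w_ff > 0:
                e_elec_cross += w_ff * el_full
                e_st_cross += w_ff * (e_env + e_lnk0_octd + e_lnkd_oct0 + st_dna_full)

            # full x bare final core
            e_elec_cross += el_core
            e_st_cross += e_env + e_lnk0_octd + st_dna_core

            if d == 2:
                anch_d = (
                    self._shift(anchors[0][None, :], screw, d, cache)[0],
                    self._shift(anchors[1][None, :], screw, d, cache)[0],
                )
                e_stack = (N - 2) * _stack_pair_energy(anchors, anch_d, m.stacking)

        e_elastic = (N - 1) * linker.elastic_energy
        e_elec = (N - 1) * e_elec_self + e_elec_cross
        e_steric = (N - 1) * e_st_self + e_st_cross
        return EnergyBreakdown(
            elastic=e_elastic / N,
            electrostatic=e_elec / N,
            steric=e_steric / N,
            stacking=e_stack / N,
        )


def _coulomb_sum(dv: np.ndarray, model: ElectrostaticsModel) -> float:
    dv = dv[dv < model.cutoff]
    if dv.size == 0:
        return 0.0
    if np.any(dv < 0.1):
        raise ValueError("overlapping charge sites (d < 0.1 A)")
    q2 = model.charge**2
    if model.shifted:
        return float(model.scale * q2 * np.sum(1.0 / dv - 1.0 / model.cutoff))
    return float(model.scale * q2 * np.sum(1.0 / dv))


def total_energy(
    params: FiberParams,
    core: NucleosomeCore,
    models: EnergyModels | None = None,
    linker: LinkerConformation | None = None,
    N: int | None = None,
) -> tuple[EnergyBreakdown, LinkerConformation]:
    """Build the fiber, optimize its (unique) linker, evaluate all terms.

    The linker connecting consecutive nucleosomes is optimized once and
    reused across the regular fiber; the best converged twist topoisomer is
    chosen by elastic energy.  Returns the per-nucleosome breakdown and the
    linker used.
    """
    from .linker_mechanics import optimize_linker

    core_ = core
    if linker is None:
        frames = place_nucleosomes(params)
        if params.N < 2:
            raise ValueError("total_energy needs at least 2 nucleosomes")
        exit_R, exit_o = compose_frames(frames[0], core_.exit_R, core_.exit_o)
        entry_R, entry_o = compose_frames(frames[1], core_.entry_R, core_.entry_o)
        stiff = models.stiffness if models is not None else None
        sols = optimize_linker(exit_R, exit_o, entry_R, entry_o, params.L, stiffness=stiff)
        linker = next(c for c in sols if c.converged)
    ev = FiberEnergyEvaluator(core_, models)
    return ev.evaluate(params, linker, N=N), linker
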