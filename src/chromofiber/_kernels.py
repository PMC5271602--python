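"""Numerical kernels for the pairwise sums that dominate runtime.

Plain-Python loops compiled with numba where available; the public modules
fall back to their vectorized numpy paths when numba is not importable, so
the package works (more slowly) without it.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in the supported env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=True)
def cross_block_sums(
    pts: np.ndarray,
    pts_d: np.ndarray,
    unit_shift: int,
    n_core: int,
    cutoff: float,
    dna_diam: float,
    min_chain_sep: int,
    k_dna: float,
    cap: float,
):
    """Electrostatic and DNA-DNA steric sums between two unit blocks.

    Returns (coulomb_sum_full, coulomb_sum_corepart, steric_full,
    steric_corepart, min_dist): the Coulomb kernel sum of 1/d - 1/cutoff
    over pairs below the cutoff, with chain-adjacent pairs (sequence
    separation < 2 across ``unit_shift``) excluded, plus the capped
    soft-core DNA overlap sums; the *_corepart variants restrict the second
    block to its first ``n_core`` points (the bare final core).
    """
    m = pts.shape[0]
    md = pts_d.shape[0]
    c_full = 0.0
    c_core = 0.0
    s_full = 0.0
    s_core = 0.0
    dmin = 1e30
    for i in range(m):
        xi, yi, zi = pts[i, 0], pts[i, 1], pts[i, 2]
        for j in range(md):
            sep = j + unit_shift - i
            if sep < 0:
                sep = -sep
            dx = pts_d[j, 0] - xi
            dy = pts_d[j, 1] - yi
            dz = pts_d[j, 2] - zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < dmin:
                dmin = d2
            if d2 >= cutoff * cutoff:
                continue
            d = np.sqrt(d2)
            if sep >= 2:
                val = 1.0 / d - 1.0 / cutoff
                c_full += val
                if j < n_core:
                    c_core += val
            if sep >= min_chain_sep and d < dna_diam:
                depth = dna_diam - d
                e = k_dna * depth * depth
                if e > cap:
                    e = cap
                s_full += e
                if j < n_core:
                    s_core += e
    return c_full, c_core, s_full, s_core, np.sqrt(dmin)


@njit(cache=True, fastmath=True)
def self_block_sums(
    pts: np.ndarray,
    n_core: int,
    cutoff: float,
    dna_diam: float,
    min_chain_sep: int,
    k_dna: float,
    cap: float,
):
    """Within-unit Coulomb and DNA steric sums.

    Intra-core pairs are excluded (the rigid core's internal energy is a
    constant); chain-adjacent pairs likewise.  Returns (coulomb, steric,
    min_dist over counted Coulomb pairs).
    """
    m = pts.shape[0]
    c = 0.0
    s = 0.0
    dmin = 1e30
    for i in range(m):
        for j in range(i + 1, m):
            if i < n_core and j < n_core:
                continue
            sep = j - i
            dx = pts[j, 0] - pts[i, 0]
            dy = pts[j, 1] - pts[i, 1]
            dz = pts[j, 2] - pts[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= cutoff * cutoff:
                continue
            d = np.sqrt(d2)
            if sep >= 2:
                c += 1.0 / d - 1.0 / cutoff
                if d2 < dmin:
                    dmin = d2
            if sep >= min_chain_sep and d < dna_diam:
                depth = dna_diam - d
                e = k_dna * depth * depth
                if e > cap:
                    e = cap
                s += e
    return c, s, np.sqrt(dmin)


@njit(cache=True, fastmath=True)
def pair_omega(
    a1x, a1y, a1z, a2x, a2y, a2z, b1x, b1y, b1z, b2x, b2y, b2z
) -> float:
    """Solid-angle contribution of one segment pair (Omega / 4 pi)."""
    u1x, u1y, u1z = b1x - a1x, b1y - a1y, b1z - a1z
    u2x, u2y, u2z = b2x - a1x, b2y - a1y, b2z - a1z
    u3x, u3y, u3z = b2x - a2x, b2y - a2y, b2z - a2z
    u4x, u4y, u4z = b1x - a2x, b1y - a2y, b1z - a2z
    n1 = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
    n2 = np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
    n3 = np.sqrt(u3x * u3x + u3y * u3y + u3z * u3z)
    n4 = np.sqrt(u4x * u4x + u4y * u4y + u4z * u4z)
    if n1 < 1e-9 or n2 < 1e-9 or n3 < 1e-9 or n4 < 1e-9:
        return 0.0
    u1x, u1y, u1z = u1x / n1, u1y / n1, u1z / n1
    u2x, u2y, u2z = u2x / n2, u2y / n2, u2z / n2
    u3x, u3y, u3z = u3x / n3, u3y / n3, u3z / n3
    u4x, u4y, u4z = u4x / n4, u4y / n4, u4z / n4
    cx = u2y * u3z - u2z * u3y
    cy = u2z * u3x - u2x * u3z
    cz = u2x * u3y - u2y * u3x
    num = u1x * cx + u1y * cy + u1z * cz
    den = (
        1.0
        + (u1x * u2x + u1y * u2y + u1z * u2z)
        + (u2x * u3x + u2y * u3y + u2z * u3z)
        + (u3x * u1x + u3y * u1y + u3z * u1z)
    )
    om = 2.0 * np.arctan2(num, den)
    cx = u3y * u4z - u3z * u4y
    cy = u3z * u4x - u3x * u4z
    cz = u3x * u4y - u3y * u4x
    num = u1x * cx + u1y * cy + u1z * cz
    den = (
        1.0
        + (u1x * u3x + u1y * u3y + u1z * u3z)
        + (u3x * u4x + u3y * u4y + u3z * u4z)
        + (u4x * u1x + u4y * u1y + u4z * u1z)
    )
    om += 2.0 * np.arctan2(num, den)
    return -om / (4.0 * np.pi)


@njit(cache=True, fastmath=True)
def self_writhe_sum(segs: np.ndarray) -> float:
    """Self-writhe of an open segment block (non-adjacent pairs, x2)."""
    n = segs.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            total += pair_omega(
                segs[i, 0, 0], segs[i, 0, 1], segs[i, 0, 2],
                segs[i, 1, 0], segs[i, 1, 1], segs[i, 1, 2],
                segs[j, 0, 0], segs[j, 0, 1], segs[j, 0, 2],
                segs[j, 1, 0], segs[j, 1, 1], segs[j, 1, 2],
            )
    return 2.0 * total


@njit(cache=True, fastmath=True)
def writhe_block_sum(seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Gauss-map solid-angle sum between two segment blocks (x2 factor).

    ``seg_a``/``seg_b`` are (n, 2, 3); pairs sharing an endpoint contribute
    zero.  Matches :func:`chromofiber.dna_topology.writhe_block`.
    """
    total = 0.0
    for i in range(seg_a.shape[0]):
        for j in range(seg_b.shape[0]):
            total += pair_omega(
                seg_a[i, 0, 0], seg_a[i, 0, 1], seg_a[i, 0, 2],
                seg_a[i, 1, 0], seg_a[i, 1, 1], seg_a[i, 1, 2],
                seg_b[j, 0, 0], seg_b[j, 0, 1], seg_b[j, 0, 2],
                seg_b[j, 1, 0], seg_b[j, 1, 1], seg_b[j, 1, 2],
            )
    return 2.0 * total
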