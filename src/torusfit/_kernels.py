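"""Numba hot loops: pair-distance histograms and tail growth.

Pure computational kernels behind :mod:`saxs_core` and :mod:`assembly`;
no public API.  Everything is written with explicit loops and early exits
because the clash checks and pair sums dominate the pipeline's runtime.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pair_hist_uniform(coords, inv_bin, nbins):
    """Unordered pair-distance histogram, unit weights, count doubled.

    Also accumulates the first and second moments of distance per bin so
    callers can evaluate the scattering kernel at each bin's weighted mean
    distance with a second-order (within-bin variance) correction.
    """
    n = coords.shape[0]
    hist = np.zeros(nbins)
    dsum = np.zeros(nbins)
    d2sum = np.zeros(nbins)
    for i in range(n):
        xi, yi, zi = coords[i, 0], coords[i, 1], coords[i, 2]
        for j in range(i + 1, n):
            dx = xi - coords[j, 0]
            dy = yi - coords[j, 1]
            dz = zi - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            d = np.sqrt(d2)
            b = int(d * inv_bin)
            hist[b] += 2.0
            dsum[b] += 2.0 * d
            d2sum[b] += 2.0 * d2
    return hist, dsum, d2sum


@njit(cache=True)
def pair_hist_weighted(coords, weights, inv_bin, nbins):
    """Unordered weighted pair-distance histogram, contribution doubled.

    ``dsum``/``d2sum`` carry the weighted first and second distance
    moments per bin (see :func:`pair_hist_uniform`).
    """
    n = coords.shape[0]
    hist = np.zeros(nbins)
    dsum = np.zeros(nbins)
    d2sum = np.zeros(nbins)
    for i in range(n):
        xi, yi, zi = coords[i, 0], coords[i, 1], coords[i, 2]
        wi = weights[i]
        for j in range(i + 1, n):
            dx = xi - coords[j, 0]
            dy = yi - coords[j, 1]
            dz = zi - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            d = np.sqrt(d2)
            w2 = 2.0 * wi * weights[j]
            b = int(d * inv_bin)
            hist[b] += w2
            dsum[b] += w2 * d
            d2sum[b] += w2 * d2
    return hist, dsum, d2sum


@njit(cache=True)
def _clear_of(points, n_points, x, y, z, cut2, skip):
    """True if (x, y, z) is at least sqrt(cut2) from points[:n_points] (skip one index)."""
    for j in range(n_points):
        if j == skip:
            continue
        dx = x - points[j, 0]
        dy = y - points[j, 1]
        dz = z - points[j, 2]
        if dx * dx + dy * dy + dz * dz < cut2:
            return False
    return True


@njit(cache=True)
def grow_conformer(
    rng,
    core,            # (n_core, 3) static obstacles
    anchors,         # (m, 3) last core bead of each chain
    prev_beads,      # (m, 3) second-to-last core bead (defines first bond angle)
    anchor_idx,      # (m,) index of each anchor within `core`
    L,               # tail beads per chain
    bond, cutoff, angle_lo, angle_hi,
    step_attempts, chain_restarts,
):
    """Grow self-avoiding tails for all chains of one conformer attempt.

    Returns ``(tails, failed_chain)`` where ``tails`` is ``(m * L, 3)`` and
    ``failed_chain`` is -1 on success or the index of the chain whose
    per-attempt restart budget (``chain_restarts``) ran out -- the caller
    then regrows the whole conformer from a fresh substream, since a dead
    end may be created by earlier chains' tails.  Each new bead keeps
    ``bond`` length, a virtual bond angle uniform in
    ``[angle_lo, angle_hi]`` (radians, dihedral free), and distance
    ``cutoff`` to every non-bonded bead already placed.
    """
    m = anchors.shape[0]
    n_core = core.shape[0]
    tails = np.empty((m * L, 3))
    cut2 = cutoff * cutoff
    two_pi = 2.0 * np.pi
    for ci in range(m):
        base = ci * L
        chain_done = False
        for _attempt in range(chain_restarts):
            # direction of the anchoring bond
            dx = anchors[ci, 0] - prev_beads[ci, 0]
            dy = anchors[ci, 1] - prev_beads[ci, 1]
            dz = anchors[ci, 2] - prev_beads[ci, 2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            ux, uy, uz = dx / norm, dy / norm, dz / norm
            lx, ly, lz = anchors[ci, 0], anchors[ci, 1], anchors[ci, 2]
            grown = 0
            while grown < L:
                placed = False
                for _a in range(step_attempts):
                    theta = rng.uniform(angle_lo, angle_hi)
                    phi = rng.uniform(0.0, two_pi)
                    beta = np.pi - theta
                    sb = np.sin(beta)
                    # orthonormal frame (e1, e2, u)
                    if abs(ux) < 0.9:
                        e1x, e1y, e1z = 0.0, uz, -uy     # cross(u, x-hat)... see below
                        # actually cross(x-hat, u) = (0, -uz, uy); any perpendicular works
                    else:
                        e1x, e1y, e1z = -uz, 0.0, ux     # perpendicular via y-hat
                    en = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                    e1x, e1y, e1z = e1x / en, e1y / en, e1z / en
                    e2x = uy * e1z - uz * e1y
                    e2y = uz * e1x - ux * e1z
                    e2z = ux * e1y - uy * e1x
                    ca, sa = np.cos(phi), np.sin(phi)
                    vx = sb * (ca * e1x + sa * e2x) + np.cos(beta) * ux
                    vy = sb * (ca * e1y + sa * e2y) + np.cos(beta) * uy
                    vz = sb * (ca * e1z + sa * e2z) + np.cos(beta) * uz
                    cx = lx + bond * vx
                    cy = ly + bond * vy
                    cz = lz + bond * vz
                    # clash vs static core (anchor exempt for the first bead)
                    skip = anchor_idx[ci] if grown == 0 else -1
                    if not _clear_of(core, n_core, cx, cy, cz, cut2, skip):
                        continue
                    # clash vs completed chains' tails
                    if not _clear_of(tails, base, cx, cy, cz, cut2, -1):
                        continue
                    # clash vs own chain minus the bonded predecessor
                    if grown >= 2 and not _clear_of(
                            tails[base:], grown - 1, cx, cy, cz, cut2, -1):
                        continue
                    placed = True
                    break
                if not placed:
                    break
                tails[base + grown, 0] = cx
                tails[base + grown, 1] = cy
                tails[base + grown, 2] = cz
                nx, ny, nz = cx - lx, cy - ly, cz - lz
                nn = np.sqrt(nx * nx + ny * ny + nz * nz)
                ux, uy, uz = nx / nn, ny / nn, nz / nn
                lx, ly, lz = cx, cy, cz
                grown += 1
            if grown == L:
                chain_done = True
                break
        if not chain_done:
            return tails, ci
    return tails, -1
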