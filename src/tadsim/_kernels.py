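"""Numba kernels: cell lists, Monte Carlo sweeps, forces and push-off.

Everything here works on flat float64/int64 arrays; the Python-facing
wrappers live in :mod:`tadsim.engine`, :mod:`tadsim.soft` and
:mod:`tadsim.builder`.  Positions are stored wrapped in [0, L) and all
pair geometry uses the minimum-image convention.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _min_image(d: float, L: float) -> float:
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True, inline="always")
def _wrap(x: float, L: float) -> float:
    return x - L * math.floor(x / L)


@njit(cache=True)
def cell_grid_shape(box: np.ndarray, cutoff: float) -> tuple[int, int, int]:
    """Cells per dimension (edge >= cutoff); any dim < 3 disables cells."""
    nx = int(box[0] / cutoff)
    ny = int(box[1] / cutoff)
    nz = int(box[2] / cutoff)
    return nx, ny, nz


@njit(cache=True)
def _build_cell_list(pos, box, nx, ny, nz):
    n = pos.shape[0]
    ncell = nx * ny * nz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    prv = np.full(n, -1, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * nx) % nx
        iy = int(pos[i, 1] / box[1] * ny) % ny
        iz = int(pos[i, 2] / box[2] * nz) % nz
        c = (ix * ny + iy) * nz + iz
        cell_of[i] = c
        nxt[i] = head[c]
        if head[c] >= 0:
            prv[head[c]] = i
        prv[i] = -1
        head[c] = i
    return head, nxt, prv, cell_of


@njit(cache=True, inline="always")
def _cell_index(x, y, z, box, nx, ny, nz):
    ix = int(x / box[0] * nx) % nx
    iy = int(y / box[1] * ny) % ny
    iz = int(z / box[2] * nz) % nz
    return (ix * ny + iy) * nz + iz


@njit(cache=True)
def _move_between_cells(i, c_old, c_new, head, nxt, prv, cell_of):
    if c_old == c_new:
        return
    # unlink from old cell
    if prv[i] >= 0:
        nxt[prv[i]] = nxt[i]
    else:
        head[c_old] = nxt[i]
    if nxt[i] >= 0:
        prv[nxt[i]] = prv[i]
    # push onto new cell
    nxt[i] = head[c_new]
    if head[c_new] >= 0:
        prv[head[c_new]] = i
    prv[i] = -1
    head[c_new] = i
    cell_of[i] = c_new


@njit(cache=True)
def brute_pairs(pos, box, cutoff):
    """All pairs (i < j) within cutoff under minimum image (O(N^2))."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    cap = 64 + n * 64
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            if dx * dx + dy * dy + dz * dz <= c2:
                if m >= cap:
                    cap *= 2
                    new = np.empty((cap, 2), dtype=np.int64)
                    new[:m] = out[:m]
                    out = new
                out[m, 0] = i
                out[m, 1] = j
                m += 1
    return out[:m].copy()


@njit(cache=True)
def cell_pairs(pos, box, cutoff, nx, ny, nz):
    """All pairs (i < j) within cutoff via a linked cell list."""
    head, nxt, prv, cell_of = _build_cell_list(pos, box, nx, ny, nz)
    n = pos.shape[0]
    c2 = cutoff * cutoff
    cap = 64 + n * 64
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * nx) % nx
        iy = int(pos[i, 1] / box[1] * ny) % ny
        iz = int(pos[i, 2] / box[2] * nz) % nz
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    c = (((ix + ox) % nx) * ny + ((iy + oy) % ny)) * nz + (iz + oz) % nz
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz <= c2:
                                if m >= cap:
                                    cap *= 2
                                    new = np.empty((cap, 2), dtype=np.int64)
                                    new[:m] = out[:m]
                                    out = new
                                out[m, 0] = i
                                out[m, 1] = j
                                m += 1
                        j = nxt[j]
    return out[:m].copy()


@njit(cache=True)
def count_hard_overlaps(pos, radii, box):
    """Number of hard-core overlapping pairs (strict r < R_i + R_j), O(N^2)."""
    n = pos.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            s = radii[i] + radii[j]
            if dx * dx + dy * dy + dz * dz < s * s:
                count += 1
    return count


@njit(cache=True)
def count_bond_violations(pos, box, bonds, r_min, r_max):
    """Bonds outside their hard window [r_min, r_max)."""
    count = 0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < r_min[b] or r >= r_max[b]:
            count += 1
    return count


@njit(cache=True, inline="always")
def _fisher_yates(order):
    for k in range(order.shape[0] - 1, 0, -1):
        j = np.random.randint(0, k + 1)
        tmp = order[k]
        order[k] = order[j]
        order[j] = tmp


@njit(cache=True)
def run_hard(pos, radii, box, adj, adj_rmax2, mobile, sigma, n_sweeps, seed,
             use_cells, cutoff):
    """Hard-mode dynamic MC: one Gaussian trial move per mobile bead per
    sweep, visited in a fresh random permutation; accept iff the moved
    bead's final hard energy is zero.  Mutates ``pos``; returns per-bead
    acceptance counts.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    accepts = np.zeros(n, dtype=np.int64)
    n_mobile = 0
    for i in range(n):
        if mobile[i]:
            n_mobile += 1
    order = np.empty(n_mobile, dtype=np.int64)
    k = 0
    for i in range(n):
        if mobile[i]:
            order[k] = i
            k += 1

    nx, ny, nz = cell_grid_shape(box, cutoff)
    if use_cells:
        head, nxt, prv, cell_of = _build_cell_list(pos, box, nx, ny, nz)
    else:
        head = np.empty(0, dtype=np.int64)
        nxt = np.empty(0, dtype=np.int64)
        prv = np.empty(0, dtype=np.int64)
        cell_of = np.empty(0, dtype=np.int64)

    for _ in range(n_sweeps):
        _fisher_yates(order)
        for k in range(n_mobile):
            i = order[k]
            tx = _wrap(pos[i, 0] + sigma[i] * np.random.normal(), box[0])
            ty = _wrap(pos[i, 1] + sigma[i] * np.random.normal(), box[1])
            tz = _wrap(pos[i, 2] + sigma[i] * np.random.normal(), box[2])

            ok = True
            # bond windows (upper edge; the core is covered by the overlap scan)
            for a in range(2):
                j = adj[i, a]
                if j < 0:
                    break
                dx = _min_image(tx - pos[j, 0], box[0])
                dy = _min_image(ty - pos[j, 1], box[1])
                dz = _min_image(tz - pos[j, 2], box[2])
                if dx * dx + dy * dy + dz * dz >= adj_rmax2[i, a]:
                    ok = False
                    break
            if ok:
                if use_cells:
                    ix = int(tx / box[0] * nx) % nx
                    iy = int(ty / box[1] * ny) % ny
                    iz = int(tz / box[2] * nz) % nz
                    for ox in range(-1, 2):
                        if not ok:
                            break
                        for oy in range(-1, 2):
                            if not ok:
                                break
                            for oz in range(-1, 2):
                                c = (((ix + ox) % nx) * ny + ((iy + oy) % ny)) * nz \
                                    + (iz + oz) % nz
                                j = head[c]
                                while j >= 0:
                                    if j != i:
                                        dx = _min_image(tx - pos[j, 0], box[0])
                                        dy = _min_image(ty - pos[j, 1], box[1])
                                        dz = _min_image(tz - pos[j, 2], box[2])
                                        s = radii[i] + radii[j]
                                        if dx * dx + dy * dy + dz * dz < s * s:
                                            ok = False
                                            break
                                    j = nxt[j]
                                if not ok:
                                    break
                else:
                    for j in range(n):
                        if j == i:
                            continue
                        dx = _min_image(tx - pos[j, 0], box[0])
                        dy = _min_image(ty - pos[j, 1], box[1])
                        dz = _min_image(tz - pos[j, 2], box[2])
                        s = radii[i] + radii[j]
                        if dx * dx + dy * dy + dz * dz < s * s:
                            ok = False
                            break
            if ok:
                pos[i, 0] = tx
                pos[i, 1] = ty
                pos[i, 2] = tz
                accepts[i] += 1
                if use_cells:
                    c_new = _cell_index(tx, ty, tz, box, nx, ny, nz)
                    _move_between_cells(i, cell_of[i], c_new, head, nxt, prv,
                                        cell_of)
    return accepts


@njit(cache=True, inline="always")
def _wca_e(r2, R_W, u_W):
    """WCA energy from squared separation; inf at r ~ 0."""
    cut2 = (WCA_CUT * R_W) * (WCA_CUT * R_W)
    if r2 >= cut2:
        return 0.0
    if r2 < 1e-18 * R_W * R_W:
        return math.inf
    s2 = R_W * R_W / r2
    s6 = s2 * s2 * s2
    return 4.0 * u_W * (s6 * s6 - s6 + 0.25)


@njit(cache=True)
def cell_pairs_shell(pos, box, cutoff):
    """All pairs within cutoff using cells of edge ~cutoff/2 and a +/-2
    shell scan; falls back to the O(N^2) scan when the box is too thin
    for a duplicate-free periodic scan in some dimension.
    """
    half = 0.5 * cutoff
    nx = int(box[0] / half)
    ny = int(box[1] / half)
    nz = int(box[2] / half)
    if nx < 1 or ny < 1 or nz < 1:
        return brute_pairs(pos, box, cutoff)
    sx = int(math.ceil(cutoff / (box[0] / nx)))
    sy = int(math.ceil(cutoff / (box[1] / ny)))
    sz = int(math.ceil(cutoff / (box[2] / nz)))
    if nx < 2 * sx + 1 or ny < 2 * sy + 1 or nz < 2 * sz + 1:
        return brute_pairs(pos, box, cutoff)
    head, nxt, prv, cell_of = _build_cell_list(pos, box, nx, ny, nz)
    n = pos.shape[0]
    c2 = cutoff * cutoff
    cap = 64 + n * 64
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * nx) % nx
        iy = int(pos[i, 1] / box[1] * ny) % ny
        iz = int(pos[i, 2] / box[2] * nz) % nz
        for ox in range(-sx, sx + 1):
            for oy in range(-sy, sy + 1):
                for oz in range(-sz, sz + 1):
                    c = (((ix + ox) % nx) * ny + ((iy + oy) % ny)) * nz \
                        + (iz + oz) % nz
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz <= c2:
                                if m >= cap:
                                    cap *= 2
                                    new = np.empty((cap, 2), dtype=np.int64)
                                    new[:m] = out[:m]
                                    out = new
                                out[m, 0] = i
                                out[m, 1] = j
                                m += 1
                        j = nxt[j]
    return out[:m].copy()


@njit(cache=True)
def _rebuild_verlet(pos, radii, box, skin, neigh, n_neigh, pos0):
    """Per-bead Verlet lists: j is a neighbour of i if their separation is
    below the pair's WCA cutoff 2^(1/6) (R_i + R_j) plus ``skin``.

    Built through a cell grid sized for the largest pair cutoff, falling
    back to the O(N^2) scan in thin boxes.  Stores the build positions in
    ``pos0`` for the displacement (half-skin) rebuild criterion.
    """
    n = pos.shape[0]
    cap = neigh.shape[1]
    r_max = 0.0
    for i in range(n):
        if radii[i] > r_max:
            r_max = radii[i]
    cutoff = WCA_CUT * 2.0 * r_max + skin
    for i in range(n):
        n_neigh[i] = 0
        pos0[i, 0] = pos[i, 0]
        pos0[i, 1] = pos[i, 1]
        pos0[i, 2] = pos[i, 2]
    pairs = cell_pairs_shell(pos, box, cutoff)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        rc = WCA_CUT * (radii[i] + radii[j]) + skin
        if dx * dx + dy * dy + dz * dz < rc * rc:
            if n_neigh[i] >= cap or n_neigh[j] >= cap:
                return -1
            neigh[i, n_neigh[i]] = j
            n_neigh[i] += 1
            neigh[j, n_neigh[j]] = i
            n_neigh[j] += 1
    return 0


@njit(cache=True)
def run_soft(pos, radii, box, adj, adj_kF, adj_RF2, mobile, sigma, u_W,
             n_sweeps, seed, skin):
    """Soft-mode dynamic MC with WCA pair + FENE bond energies and the
    Metropolis test min[1, exp(-dU)].  Mutates ``pos``; returns per-bead
    acceptance counts.

    Pair energies use per-bead Verlet lists with a ``skin`` margin,
    rebuilt whenever the two largest displacements since the last build
    could bridge the skin.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    accepts = np.zeros(n, dtype=np.int64)
    n_mobile = 0
    for i in range(n):
        if mobile[i]:
            n_mobile += 1
    order = np.empty(n_mobile, dtype=np.int64)
    k = 0
    for i in range(n):
        if mobile[i]:
            order[k] = i
            k += 1

    cap = 32
    while True:
        neigh = np.empty((n, cap), dtype=np.int64)
        n_neigh = np.empty(n, dtype=np.int64)
        pos0 = np.empty((n, 3), dtype=np.float64)
        if _rebuild_verlet(pos, radii, box, skin, neigh, n_neigh, pos0) == 0:
            break
        cap *= 2
    max_disp = 0.0

    for _ in range(n_sweeps):
        _fisher_yates(order)
        for k in range(n_mobile):
            i = order[k]
            tx = _wrap(pos[i, 0] + sigma[i] * np.random.normal(), box[0])
            ty = _wrap(pos[i, 1] + sigma[i] * np.random.normal(), box[1])
            tz = _wrap(pos[i, 2] + sigma[i] * np.random.normal(), box[2])
            # WCA with Verlet neighbours: old and new in one pass
            e_new = 0.0
            e_old = 0.0
            for a in range(n_neigh[i]):
                j = neigh[i, a]
                R_W = radii[i] + radii[j]
                dx = _min_image(tx - pos[j, 0], box[0])
                dy = _min_image(ty - pos[j, 1], box[1])
                dz = _min_image(tz - pos[j, 2], box[2])
                e_new += _wca_e(dx * dx + dy * dy + dz * dz, R_W, u_W)
                if e_new == math.inf:
                    break
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                e_old += _wca_e(dx * dx + dy * dy + dz * dz, R_W, u_W)
            if e_new == math.inf:
                continue
            # FENE bonds
            reject = False
            for a in range(2):
                j = adj[i, a]
                if j < 0:
                    break
                RF2 = adj_RF2[i, a]
                dx = _min_image(tx - pos[j, 0], box[0])
                dy = _min_image(ty - pos[j, 1], box[1])
                dz = _min_image(tz - pos[j, 2], box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= RF2:
                    reject = True
                    break
                e_new += -0.5 * adj_kF[i, a] * RF2 * math.log(1.0 - r2 / RF2)
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < RF2:
                    e_old += -0.5 * adj_kF[i, a] * RF2 * math.log(1.0 - r2 / RF2)
            if reject:
                continue
            du = e_new - e_old
            if du <= 0.0 or np.random.random() < math.exp(-du):
                pos[i, 0] = tx
                pos[i, 1] = ty
                pos[i, 2] = tz
                accepts[i] += 1
                dx = _min_image(tx - pos0[i, 0], box[0])
                dy = _min_image(ty - pos0[i, 1], box[1])
                dz = _min_image(tz - pos0[i, 2], box[2])
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d > max_disp:
                    max_disp = d
        if 2.0 * max_disp >= skin:
            while _rebuild_verlet(pos, radii, box, skin, neigh, n_neigh,
                                  pos0) != 0:
                cap *= 2
                neigh = np.empty((n, cap), dtype=np.int64)
            max_disp = 0.0
    return accepts


@njit(cache=True)
def soft_forces_virial(pos, radii, box, bonds, bond_kF, bond_RF, u_W):
    """Total soft energy, per-bead forces and the virial tensor.

    The virial is sum over pairs of the outer product f_ij (x) r_ij with
    r_ij the minimum-image separation; WCA acts between every pair within
    its cutoff (bonded or not), FENE only along bonds.  O(N^2) pair loop.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3), dtype=np.float64)
    virial = np.zeros((3, 3), dtype=np.float64)
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            R_W = radii[i] + radii[j]
            cut2 = (WCA_CUT * R_W) * (WCA_CUT * R_W)
            if r2 < cut2:
                s2 = R_W * R_W / r2
                s6 = s2 * s2 * s2
                energy += 4.0 * u_W * (s6 * s6 - s6 + 0.25)
                # f = -dU/dr / r  (positive => repulsive along r_ij)
                fpr = 4.0 * u_W * (12.0 * s6 * s6 - 6.0 * s6) / r2
                fx = fpr * dx
                fy = fpr * dy
                fz = fpr * dz
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
                virial[0, 0] += fx * dx
                virial[0, 1] += fx * dy
                virial[0, 2] += fx * dz
                virial[1, 0] += fy * dx
                virial[1, 1] += fy * dy
                virial[1, 2] += fy * dz
                virial[2, 0] += fz * dx
                virial[2, 1] += fz * dy
                virial[2, 2] += fz * dz
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r2 = dx * dx + dy * dy + dz * dz
        RF2 = bond_RF[b] * bond_RF[b]
        if r2 >= RF2:
            energy = math.inf
            continue
        energy += -0.5 * bond_kF[b] * RF2 * math.log(1.0 - r2 / RF2)
        fpr = -bond_kF[b] / (1.0 - r2 / RF2)  # attractive
        fx = fpr * dx
        fy = fpr * dy
        fz = fpr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += fx * dx
        virial[0, 1] += fx * dy
        virial[0, 2] += fx * dz
        virial[1, 0] += fy * dx
        virial[1, 1] += fy * dy
        virial[1, 2] += fy * dz
        virial[2, 0] += fz * dx
        virial[2, 1] += fz * dy
        virial[2, 2] += fz * dz
    return energy, forces, virial


@njit(cache=True)
def pushoff_sweeps(pos, radii, box, bonds, bond_rmin, bond_rmax, scale,
                   max_sweeps, gain):
    """Athermal overlap relaxation at radius scale ``scale``.

    Each sweep pushes every overlapping pair apart along their centre
    line (Jacobi accumulation) and then projects bonds back into their
    hard window.  Returns the number of remaining violations.
    """
    n = pos.shape[0]
    disp = np.zeros((n, 3), dtype=np.float64)
    r_max = 0.0
    for i in range(n):
        if radii[i] > r_max:
            r_max = radii[i]
    cutoff = 2.0 * r_max * scale
    for sweep_no in range(max_sweeps):
        n_bad = 0
        for i in range(n):
            disp[i, 0] = 0.0
            disp[i, 1] = 0.0
            disp[i, 2] = 0.0
        pairs = cell_pairs_shell(pos, box, cutoff)
        for p in range(pairs.shape[0]):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            s = (radii[i] + radii[j]) * scale
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < s * s:
                n_bad += 1
                r = math.sqrt(r2)
                if r < 1e-12:
                    dx, dy, dz = s, 0.0, 0.0
                    r = s
                push = gain * (s - r + 1e-6) * 0.5 / r
                disp[i, 0] += push * dx
                disp[i, 1] += push * dy
                disp[i, 2] += push * dz
                disp[j, 0] -= push * dx
                disp[j, 1] -= push * dy
                disp[j, 2] -= push * dz
        for i in range(n):
            pos[i, 0] = _wrap(pos[i, 0] + disp[i, 0], box[0])
            pos[i, 1] = _wrap(pos[i, 1] + disp[i, 1], box[1])
            pos[i, 2] = _wrap(pos[i, 2] + disp[i, 2], box[2])
        # project bonds back into [r_min, r_max)
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            lo = bond_rmin[b] * scale
            hi = bond_rmax[b]
            target = -1.0
            if r >= hi:
                target = lo + 0.9 * (hi - lo)
                n_bad += 1
            elif r < lo:
                target = lo + 0.05 * (hi - lo)
            if target > 0.0 and r > 1e-12:
                f = 0.5 * (target / r - 1.0)
                pos[i, 0] = _wrap(pos[i, 0] + f * dx, box[0])
                pos[i, 1] = _wrap(pos[i, 1] + f * dy, box[1])
                pos[i, 2] = _wrap(pos[i, 2] + f * dz, box[2])
                pos[j, 0] = _wrap(pos[j, 0] - f * dx, box[0])
                pos[j, 1] = _wrap(pos[j, 1] - f * dy, box[1])
                pos[j, 2] = _wrap(pos[j, 2] - f * dz, box[2])
        if n_bad == 0:
            return 0
    # final count at full window
    bad = count_hard_overlaps(pos, radii * scale, box)
    bad += count_bond_violations(pos, box, bonds, bond_rmin * scale, bond_rmax)
    return bad
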