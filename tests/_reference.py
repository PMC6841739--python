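"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written as directly as possible from the definitions
(double loops over cells and time origins, scalar step-by-step recursions)
and is deliberately independent of the vectorized production code paths.
"""

from __future__ import annotations

import math

import numpy as np


def naive_msd(traj, lags):
    """Ensemble MSD by explicit loops over cells and time origins."""
    values = []
    for lag in lags:
        per_cell = []
        for cid in traj.cell_ids:
            t, xy = traj.positions(cid)
            dt = t[1] - t[0]
            k = lag / dt
            if abs(k - round(k)) > 1e-9:
                continue
            k = int(round(k))
            if k == 0:
                per_cell.append(0.0)
                continue
            if k >= len(t):
                continue
            acc = 0.0
            n = 0
            for j in range(len(t) - k):
                dx = xy[j + k, 0] - xy[j, 0]
                dy = xy[j + k, 1] - xy[j, 1]
                acc += dx * dx + dy * dy
                n += 1
            per_cell.append(acc / n)
        values.append(sum(per_cell) / len(per_cell))
    return np.asarray(values)


def naive_gi(traj, cell_id, lag, bin_edges):
    """Radial density of one cell's displacements by explicit counting."""
    t, xy = traj.positions(cell_id)
    dt = t[1] - t[0]
    k = int(round(lag / dt))
    mags = []
    for j in range(len(t) - k):
        dx = xy[j + k, 0] - xy[j, 0]
        dy = xy[j + k, 1] - xy[j, 1]
        mags.append(math.hypot(dx, dy))
    dens = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        count = sum(1 for m in mags if lo <= m < hi)
        if hi == bin_edges[-1]:
            count += sum(1 for m in mags if m == hi)
        area = math.pi * (hi * hi - lo * lo)
        dens.append(count / len(mags) / area)
    return np.asarray(dens)


def naive_G(traj, lag, bin_edges):
    curves = [naive_gi(traj, cid, lag, bin_edges) for cid in traj.cell_ids]
    return np.mean(curves, axis=0)


def naive_vacf(v):
    """Normalized VACF of one velocity series by explicit origin loops."""
    n = len(v)
    num = []
    for k in range(n):
        acc = 0.0
        for j in range(n - k):
            acc += v[j][0] * v[j + k][0] + v[j][1] * v[j + k][1]
        num.append(acc / (n - k))
    return np.asarray(num) / num[0]


def naive_accel_samples(traj):
    """(speed, a_p, a_np) samples pooled over cells, by scalar arithmetic."""
    out = []
    for cid in traj.cell_ids:
        t, xy = traj.positions(cid)
        dt = t[1] - t[0]
        v = [( (xy[j+1,0]-xy[j,0])/dt, (xy[j+1,1]-xy[j,1])/dt ) for j in range(len(t)-1)]
        for j in range(len(v) - 1):
            ax = (v[j+1][0] - v[j][0]) / dt
            ay = (v[j+1][1] - v[j][1]) / dt
            speed = math.hypot(*v[j])
            if speed == 0:
                continue
            ux, uy = v[j][0] / speed, v[j][1] / speed
            out.append((speed, ax * ux + ay * uy, ax * (-uy) + ay * ux))
    return np.asarray(out)


def naive_th(params, seed):
    """Step-by-step scalar reference of the temporal-noise walk.

    Consumes randomness in the documented order: magnitude uniforms
    (n_steps, n_cells), then direction uniforms of the same shape.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(np.floor(params.duration / params.step_dt + 1e-9))
    n = params.n_cells
    u = rng.random((n_steps, n))
    theta = rng.random((n_steps, n)) * (2.0 * np.pi)
    beta = np.asarray(params.beta_source.ppf(u), dtype=float)
    positions = {}
    for i in range(n):
        pos = [(0.0, 0.0)]
        prev_x = prev_y = 0.0
        for k in range(n_steps):
            sx = beta[k, i] * np.cos(theta[k, i])
            sy = beta[k, i] * np.sin(theta[k, i])
            if k == 0:
                prev_x, prev_y = sx, sy
            else:
                prev_x = prev_x / params.A_th + sx
                prev_y = prev_y / params.A_th + sy
            pos.append((pos[-1][0] + prev_x, pos[-1][1] + prev_y))
        positions[i] = np.asarray(pos)
    return positions


def naive_cth(params, seed):
    """Scalar reference of the combined walk (per-cell grids and samplers)."""
    rng = np.random.default_rng(seed)
    positions = {}
    for i in range(params.n_cells):
        step_dt = float(params.P_i[i])
        n_steps = int(np.floor(params.duration / step_dt + 1e-9))
        u = rng.random(n_steps)
        theta = rng.random(n_steps) * (2.0 * np.pi)
        beta = np.asarray(params.beta_sources[i].ppf(u), dtype=float)
        pos = [(0.0, 0.0)]
        prev_x = prev_y = 0.0
        for k in range(n_steps):
            sx = beta[k] * np.cos(theta[k])
            sy = beta[k] * np.sin(theta[k])
            if k == 0:
                prev_x, prev_y = sx, sy
            else:
                prev_x = prev_x / params.A_cth + sx
                prev_y = prev_y / params.A_cth + sy
            pos.append((pos[-1][0] + prev_x, pos[-1][1] + prev_y))
        positions[i] = np.asarray(pos)
    return positions
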