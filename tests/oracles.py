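"""Independent numeric oracles: vectorized velocity-Verlet integration.

These deliberately avoid the package's closed forms — they step the equation
of motion directly so the analytic kinematics can be checked against them.
"""

from __future__ import annotations

import numpy as np

from plumetrace.constants import ATOMIC_MASS_UNIT, ELEMENTARY_CHARGE


def accel(mass_u: np.ndarray, charge: np.ndarray, field: np.ndarray) -> np.ndarray:
    return charge * ELEMENTARY_CHARGE * field / (mass_u * ATOMIC_MASS_UNIT)


def verlet_position(t_e, v0, mass_u, charge, field, delta_t, dt=1e-11):
    """Position at delta_t by velocity-Verlet in the uniform field.

    Vectorized over cases; ions not yet ejected stay at 0.
    """
    t_e, v0, delta_t = np.broadcast_arrays(
        np.atleast_1d(np.asarray(t_e, float)),
        np.atleast_1d(np.asarray(v0, float)),
        np.atleast_1d(np.asarray(delta_t, float)),
    )
    a = np.broadcast_to(
        accel(np.asarray(mass_u, float), np.asarray(charge, float),
              np.asarray(field, float)),
        t_e.shape,
    )
    tau = np.maximum(delta_t - t_e, 0.0)
    n_full = np.floor(tau / dt).astype(int)
    x = np.zeros_like(tau)
    v = v0.copy()
    n_max = int(n_full.max()) if n_full.size else 0
    for k in range(n_max):
        active = k < n_full
        x = np.where(active, x + v * dt + 0.5 * a * dt * dt, x)
        v = np.where(active, v + a * dt, v)
    rem = tau - n_full * dt
    x = x + v * rem + 0.5 * a * rem * rem
    return x if x.shape != (1,) else float(x[0])


def verlet_time_of_flight(t_e, v0, mass_u, charge, gap, drift_length, field,
                          dt=1e-11):
    """Detector arrival by stepping through the gap, then analytic drift.

    The gap-exit time within the final step is refined by solving the local
    quadratic, so the result is exact to floating tolerance for a uniform
    field (Verlet trajects the quadratic exactly at step boundaries).
    """
    t_e, v0 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(t_e, float)),
        np.atleast_1d(np.asarray(v0, float)),
    )
    a = np.broadcast_to(
        accel(np.asarray(mass_u, float), np.asarray(charge, float),
              np.asarray(field, float)),
        t_e.shape,
    ).astype(float)
    x = np.zeros_like(t_e)
    v = v0.astype(float).copy()
    t = np.zeros_like(t_e)
    done = np.zeros(t_e.shape, dtype=bool)
    t_exit = np.zeros_like(t_e)
    v_exit = np.zeros_like(t_e)
    # hard cap well beyond any plausible gap transit
    for _ in range(20_000_000):
        x_new = x + v * dt + 0.5 * a * dt * dt
        v_new = v + a * dt
        crossing = (~done) & (x_new >= gap)
        if crossing.any():
            # remaining distance within this step: solve s = v dt' + a dt'^2/2
            s = gap - x[crossing]
            vv = v[crossing]
            aa = a[crossing]
            dt_cross = (-vv + np.sqrt(vv * vv + 2 * aa * s)) / aa
            t_exit[crossing] = t[crossing] + dt_cross
            v_exit[crossing] = vv + aa * dt_cross
            done |= crossing
        x = np.where(done, x, x_new)
        v = np.where(done, v, v_new)
        t = t + dt * (~done)
        if done.all():
            break
    result = t_e + t_exit + drift_length / v_exit
    return result if result.shape != (1,) else float(result[0])


def brute_force_invert(z, delta_t, v0, mass_u, charge, field, step=1e-11,
                       propagate=None):
    """Scan t_E on a fine grid for the value whose propagation matches z.

    Uses the supplied forward model (default: Verlet) evaluated on a dense
    t_E grid; returns the grid point minimizing |z(t_E) - z|.
    """
    grid = np.arange(0.0, delta_t, step)
    if propagate is None:
        zs = np.array([
            verlet_position(te, v0, mass_u, charge, field, delta_t, dt=1e-10)
            for te in grid[:: max(1, len(grid) // 2000)]
        ])
        grid = grid[:: max(1, len(grid) // 2000)]
    else:
        zs = propagate(grid)
    return float(grid[np.argmin(np.abs(zs - z))])
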