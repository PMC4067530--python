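"""Compiled inner loop of the Brownian-dynamics engine.

One kernel drives all three translocation models.  The per-step update is the
second-order overdamped scheme

    x(t+dt) = x(t) + R0 + (D/kT) F dt + (D^2 / 2 (kT)^2) F F' dt^2
              + (D/kT) F' R1

with the correlated Gaussian pair Var(R0) = 2 D dt, Var(R1) = (2/3) D dt^3,
Cov(R0, R1) = D dt^2, sampled here as R1 = (dt/2) R0 + sqrt(D dt^3 / 6) Z.
Forces are harmonic restoring forces of ParA tethers, F = -k_sp (x - x_eq),
F' = -k_sp, entering only through k_sp/kT = 1/sigma^2.

Two exact algebraic reductions keep the loop fast:

* For a DNA-bound dimer the force is linear, so the full four-term update
  plus correlated noise collapses to the linear map
  ``x' = x_eq + a (x - x_eq) + s Z`` with ``a = 1 - th dt + th^2 dt^2 / 2``
  (``th = D_A/sigma^2``) and
  ``s^2 = 2 D_A dt - 2 th D_A dt^2 + (2/3) th^2 D_A dt^3`` -- the same
  jointly-Gaussian law, one draw instead of two.

* Dimers whose tether anchor lies farther than ``active_window`` from the
  complex along x cannot be captured (the window exceeds the capture radius
  plus 8 sigma) and are frozen; when the complex approaches, the position is
  resampled from the stationary Boltzmann distribution N(x_eq, sigma^2).
  Setting ``active_window >= l0`` disables the approximation.

Dimer states: 0 = DNA-bound, 1 = bound to the partition complex, 2 = free.
Models: 0 = diffusion, 1 = diffusion-binding, 2 = DNA-relay.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = 1.0e30


@njit(cache=True)
def simulate_run(
    seed,
    model,
    n_steps,
    dt,
    l0,
    w0,
    x0,
    y0,
    x_finish,
    r_cap,
    n_para,
    k_cat,
    tau_db,
    d_pc,
    d_a,
    inv_s2x,
    inv_s2y,
    record_every,
    active_window,
):
    """Simulate one trajectory; see module docstring for conventions.

    Returns (n_rec, t_rec, x_rec, y_rec, nb_rec, ndna_rec, nfree_rec,
    crossing_time, dim_x, dim_y, dim_ex, dim_ey, dim_state, dim_tev);
    crossing_time is -1.0 when the complex never reached x_finish.
    """
    np.random.seed(seed)

    # --- agents ---------------------------------------------------------
    dim_x = np.empty(n_para)
    dim_y = np.empty(n_para)
    dim_ex = np.empty(n_para)
    dim_ey = np.empty(n_para)
    dim_state = np.zeros(n_para, dtype=np.int64)
    dim_stale = np.zeros(n_para, dtype=np.int64)
    dim_tev = np.full(n_para, _INF)
    if model != 0:
        # DNA-bound at t=0, anchors drawn from the linear rebinding density
        # between the complex and the new pole (inverse CDF: sqrt(u)).
        for i in range(n_para):
            u = np.random.random()
            dim_x[i] = x0 + (l0 - x0) * np.sqrt(u)
            dim_y[i] = (np.random.random() - 0.5) * w0
            dim_ex[i] = dim_x[i]
            dim_ey[i] = dim_y[i]
            dim_stale[i] = 1

    xpc = x0
    ypc = y0

    # --- precomputed coefficients --------------------------------------
    thx = d_a * inv_s2x
    thy = d_a * inv_s2y
    ax = 1.0 - thx * dt + 0.5 * thx * thx * dt * dt
    ay = 1.0 - thy * dt + 0.5 * thy * thy * dt * dt
    sx = np.sqrt(2 * d_a * dt - 2 * thx * d_a * dt * dt + (2.0 / 3.0) * thx * thx * d_a * dt**3)
    sy = np.sqrt(2 * d_a * dt - 2 * thy * d_a * dt * dt + (2.0 / 3.0) * thy * thy * d_a * dt**3)
    sigx = np.sqrt(1.0 / inv_s2x)
    sigy = np.sqrt(1.0 / inv_s2y)
    s_r0 = np.sqrt(2 * d_pc * dt)
    c_r1 = 0.5 * dt
    s_r1 = np.sqrt(d_pc * dt**3 / 6.0)
    cap2 = r_cap * r_cap
    half_w = 0.5 * w0

    # --- recording ------------------------------------------------------
    n_rec_max = n_steps // record_every + 1
    t_rec = np.empty(n_rec_max)
    x_rec = np.empty(n_rec_max)
    y_rec = np.empty(n_rec_max)
    nb_rec = np.zeros(n_rec_max, dtype=np.int64)
    ndna_rec = np.zeros(n_rec_max, dtype=np.int64)
    nfree_rec = np.zeros(n_rec_max, dtype=np.int64)

    nab = 0
    n_dna = n_para
    n_free = 0
    t_rec[0] = 0.0
    x_rec[0] = xpc
    y_rec[0] = ypc
    nb_rec[0] = 0
    ndna_rec[0] = n_dna
    nfree_rec[0] = 0
    n_rec = 1

    t = 0.0
    crossing_time = -1.0

    for step in range(n_steps):
        t += dt

        # -- complex update ----------------------------------------------
        if model == 1 and nab > 0:
            # diffusion-binding: a rigid bond to >=1 immobile DNA-bound
            # dimer stalls the complex until hydrolysis releases it
            xnew = xpc
            ynew = ypc
        else:
            fx = 0.0
            fy = 0.0
            if model == 2 and nab > 0:
                for i in range(n_para):
                    if dim_state[i] == 1:
                        fx += -inv_s2x * (dim_x[i] - dim_ex[i])
                        fy += -inv_s2y * (dim_y[i] - dim_ey[i])
                fpx = -inv_s2x * nab
                fpy = -inv_s2y * nab
            else:
                fpx = 0.0
                fpy = 0.0

            r0 = s_r0 * np.random.normal()
            r1 = c_r1 * r0 + s_r1 * np.random.normal()
            xnew = xpc + r0 + d_pc * fx * dt + 0.5 * d_pc * d_pc * fx * fpx * dt * dt + d_pc * fpx * r1
            r0 = s_r0 * np.random.normal()
            r1 = c_r1 * r0 + s_r1 * np.random.normal()
            ynew = ypc + r0 + d_pc * fy * dt + 0.5 * d_pc * d_pc * fy * fpy * dt * dt + d_pc * fpy * r1

        if xnew >= x_finish:
            crossing_time = t
            xpc = x_finish
            ypc = ynew
            break

        # reflective walls (single fold suffices at these step sizes)
        if xnew < 0.0:
            xnew = -xnew
        elif xnew > l0:
            xnew = 2.0 * l0 - xnew
        if ynew > half_w:
            ynew = w0 - ynew
        elif ynew < -half_w:
            ynew = -w0 - ynew
        ddx = xnew - xpc
        ddy = ynew - ypc
        xpc = xnew
        ypc = ynew

        # -- dimer updates and state transitions -------------------------
        if model != 0:
            for i in range(n_para):
                s = dim_state[i]
                if s == 0:
                    if model == 2:
                        far = dim_ex[i] - xpc > active_window or xpc - dim_ex[i] > active_window
                        if far:
                            dim_stale[i] = 1
                        else:
                            if dim_stale[i] == 1:
                                dim_x[i] = dim_ex[i] + sigx * np.random.normal()
                                dim_y[i] = dim_ey[i] + sigy * np.random.normal()
                                dim_stale[i] = 0
                            else:
                                dim_x[i] = dim_ex[i] + ax * (dim_x[i] - dim_ex[i]) + sx * np.random.normal()
                                dim_y[i] = dim_ey[i] + ay * (dim_y[i] - dim_ey[i]) + sy * np.random.normal()
                            # reflect fluctuating tethers at the walls
                            if dim_x[i] < 0.0:
                                dim_x[i] = -dim_x[i]
                            elif dim_x[i] > l0:
                                dim_x[i] = 2.0 * l0 - dim_x[i]
                            if dim_y[i] > half_w:
                                dim_y[i] = w0 - dim_y[i]
                            elif dim_y[i] < -half_w:
                                dim_y[i] = -w0 - dim_y[i]
                            dxi = dim_x[i] - xpc
                            dyi = dim_y[i] - ypc
                            if dxi * dxi + dyi * dyi <= cap2:
                                dim_state[i] = 1
                                dim_tev[i] = t + np.random.exponential(1.0 / k_cat)
                                nab += 1
                                n_dna -= 1
                    else:
                        # diffusion-binding: immobile dimer, overlap test only
                        if dim_x[i] - xpc <= active_window and xpc - dim_x[i] <= active_window:
                            dxi = dim_x[i] - xpc
                            dyi = dim_y[i] - ypc
                            if dxi * dxi + dyi * dyi <= cap2:
                                dim_state[i] = 1
                                dim_tev[i] = t + np.random.exponential(1.0 / k_cat)
                                nab += 1
                                n_dna -= 1
                elif s == 1:
                    if model == 2:
                        # attached dimers inherit the complex's displacement
                        dim_x[i] += ddx
                        dim_y[i] += ddy
                    if t >= dim_tev[i]:
                        dim_state[i] = 2
                        dim_tev[i] = t + np.random.exponential(tau_db)
                        nab -= 1
                        n_free += 1
                else:
                    if t >= dim_tev[i] and xpc < l0:
                        u = np.random.random()
                        dim_x[i] = xpc + (l0 - xpc) * np.sqrt(u)
                        dim_y[i] = (np.random.random() - 0.5) * w0
                        dim_ex[i] = dim_x[i]
                        dim_ey[i] = dim_y[i]
                        dim_state[i] = 0
                        dim_stale[i] = 1
                        dim_tev[i] = _INF
                        n_free -= 1
                        n_dna += 1

        if (step + 1) % record_every == 0:
            t_rec[n_rec] = t
            x_rec[n_rec] = xpc
            y_rec[n_rec] = ypc
            nb_rec[n_rec] = nab
            ndna_rec[n_rec] = n_dna
            nfree_rec[n_rec] = n_free
            n_rec += 1

    return (
        n_rec,
        t_rec,
        x_rec,
        y_rec,
        nb_rec,
        ndna_rec,
        nfree_rec,
        crossing_time,
        dim_x,
        dim_y,
        dim_ex,
        dim_ey,
        dim_state,
        dim_tev,
    )
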