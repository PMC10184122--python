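"""JIT-compiled inner loops for the overdamped Langevin engine.

All kernels seed numpy's legacy RNG internally, so a fixed seed gives a
bit-identical trajectory.  Units: Å, ns, kcal/mol.  The mobility passed in is
mu = D / (k_B T_ref) (Å² mol kcal^-1 ns^-1); the noise amplitude follows the
fluctuation--dissipation relation at the *simulated* temperature, so T -> 0
gives deterministic steepest-descent dynamics with unchanged friction.

Random numbers are drawn through lazily refilled block buffers (vectorised
generation is ~5x faster than per-step scalar draws in compiled code); a
buffer refill never happens unless a draw is actually consumed, so disabling
noise or occupancy dynamics leaves the remaining stream untouched.
"""

import numpy as np
from numba import njit

_BLOCK = 1 << 16


@njit(cache=True, fastmath=True)
def _switch(x, cat_center, cat_width):
    """Logistic accessibility switch g(x) = 1/(1 + exp(-(x - x_c)/w))."""
    return 0.5 * (1.0 + np.tanh(0.5 * (x - cat_center) / cat_width))


@njit(cache=True, fastmath=True)
def _du_landscape(x, n, well_depth, eq_distance, steepness, cat_c, cat_center, cat_width):
    """dU/dx of the bond + catalysis landscape at occupancy n."""
    e = np.exp(-steepness * (x - eq_distance))
    du = 2.0 * steepness * well_depth * (1.0 - e) * e
    if n == 1:
        g = _switch(x, cat_center, cat_width)
        du -= cat_c * g * (1.0 - g) / cat_width
    return du


@njit(cache=True, fastmath=True)
def equilibrate_kernel(
    seed,
    x0,
    n0,
    n_steps,
    stride,
    dt,
    mobility,
    kt,
    well_depth,
    eq_distance,
    steepness,
    cat_c,
    cat_center,
    cat_width,
    shielding,
    k_in,
    k_out,
    restraint_lo,
    restraint_hi,
    restraint_k,
):
    """Restrained Brownian dynamics; records (x, n) every ``stride`` steps.

    The restraint is flat-bottom: zero force inside [lo, hi], harmonic
    k*(x-bound)^2 outside (force constant convention of biased-MD engines).
    restraint_k <= 0 disables it.  The water occupancy is a Markov jump
    process: entry probability per step (1-shielding)*k_in*g(x)*dt (water can
    only reach the acceptor while the interface is open), exit probability
    k_out*dt.  Returns (xs, ns, x_final, n_final, max_dx).
    """
    np.random.seed(seed)
    n_rec = n_steps // stride
    xs = np.empty(n_rec, dtype=np.float64)
    ns = np.empty(n_rec, dtype=np.int64)
    sigma = np.sqrt(2.0 * mobility * kt * dt)
    p_in = (1.0 - shielding) * k_in * dt
    p_out = k_out * dt
    nbuf = np.empty(_BLOCK)
    ubuf = np.empty(_BLOCK)
    ni = _BLOCK
    ui = _BLOCK
    x = x0
    n = n0
    max_dx = 0.0
    rec = 0
    for i in range(n_steps):
        if n == 0:
            if p_in > 0.0:
                if ui == _BLOCK:
                    ubuf = np.random.random(_BLOCK)
                    ui = 0
                if ubuf[ui] < p_in * _switch(x, cat_center, cat_width):
                    n = 1
                ui += 1
        elif p_out > 0.0:
            if ui == _BLOCK:
                ubuf = np.random.random(_BLOCK)
                ui = 0
            if ubuf[ui] < p_out:
                n = 0
            ui += 1
        du = _du_landscape(
            x, n, well_depth, eq_distance, steepness, cat_c, cat_center, cat_width
        )
        if restraint_k > 0.0:
            if x < restraint_lo:
                du += 2.0 * restraint_k * (x - restraint_lo)
            elif x > restraint_hi:
                du += 2.0 * restraint_k * (x - restraint_hi)
        dx = -mobility * du * dt
        if sigma > 0.0:
            if ni == _BLOCK:
                nbuf = np.random.standard_normal(_BLOCK)
                ni = 0
            dx += sigma * nbuf[ni]
            ni += 1
        adx = abs(dx)
        if adx > max_dx:
            max_dx = adx
        x += dx
        if (i + 1) % stride == 0:
            xs[rec] = x
            ns[rec] = n
            rec += 1
    return xs, ns, x, n, max_dx


@njit(cache=True, fastmath=True)
def pull_kernel(
    seed,
    x0,
    n0,
    lam0,
    lam_rate,
    spring_k,
    n_steps,
    dt,
    mobility,
    kt,
    well_depth,
    eq_distance,
    steepness,
    cat_c,
    cat_center,
    cat_width,
    shielding,
    k_in,
    k_out,
    grid,
    out_work,
):
    """Guided (steered) Brownian dynamics with work accumulation.

    The guide centre moves as λ(t) = lam0 + lam_rate * t; the particle feels
    the landscape plus the spring ½ k (x - λ)².  The external work accumulates
    as dW = k * lam_rate * (λ - x) * dt and is recorded each time λ crosses a
    point of ``grid`` (pass an empty grid to run an unrecorded approach stage).
    Returns (x_final, n_final, work_final, max_lag, max_dx, n_recorded).
    """
    np.random.seed(seed)
    sigma = np.sqrt(2.0 * mobility * kt * dt)
    p_in = (1.0 - shielding) * k_in * dt
    p_out = k_out * dt
    nbuf = np.empty(_BLOCK)
    ubuf = np.empty(_BLOCK)
    ni = _BLOCK
    ui = _BLOCK
    x = x0
    n = n0
    lam = lam0
    work = 0.0
    max_lag = 0.0
    max_dx = 0.0
    gi = 0
    ng = grid.shape[0]
    forward = lam_rate >= 0.0
    while gi < ng and (
        (forward and grid[gi] <= lam + 1e-9) or (not forward and grid[gi] >= lam - 1e-9)
    ):
        out_work[gi] = 0.0
        gi += 1
    for i in range(n_steps):
        if n == 0:
            if p_in > 0.0:
                if ui == _BLOCK:
                    ubuf = np.random.random(_BLOCK)
                    ui = 0
                if ubuf[ui] < p_in * _switch(x, cat_center, cat_width):
                    n = 1
                ui += 1
        elif p_out > 0.0:
            if ui == _BLOCK:
                ubuf = np.random.random(_BLOCK)
                ui = 0
            if ubuf[ui] < p_out:
                n = 0
            ui += 1
        du = _du_landscape(
            x, n, well_depth, eq_distance, steepness, cat_c, cat_center, cat_width
        )
        du += spring_k * (x - lam)
        dx = -mobility * du * dt
        if sigma > 0.0:
            if ni == _BLOCK:
                nbuf = np.random.standard_normal(_BLOCK)
                ni = 0
            dx += sigma * nbuf[ni]
            ni += 1
        adx = abs(dx)
        if adx > max_dx:
            max_dx = adx
        x += dx
        lam = lam0 + lam_rate * (i + 1) * dt
        work += spring_k * lam_rate * (lam - x) * dt
        lag = abs(lam - x)
        if lag > max_lag:
            max_lag = lag
        while gi < ng and (
            (forward and grid[gi] <= lam + 1e-9)
            or (not forward and grid[gi] >= lam - 1e-9)
        ):
            out_work[gi] = work
            gi += 1
    return x, n, work, max_lag, max_dx, gi
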