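"""Hot inner loops, JIT-compiled with numba when available.

The pairwise-competition loop is the only per-individual sequential loop in
the simulator (every other yearly process is a vectorized array operation).
It consumes pre-drawn uniform random numbers so the JIT-compiled and the pure
Python fallback paths produce bit-identical results from the same stream.
"""

from __future__ import annotations

import numpy as np


def _compete_loop(mass, ap, capacity, rand):  # pragma: no cover - covered via wrapper
    """Remove individuals pairwise until biomass fits the patch capacity.

    While total biomass exceeds ``capacity`` and at least two plants remain,
    draw two distinct remaining plants uniformly at random and remove the one
    with the lower precipitation adaptation ``ap`` (ties broken by a fair
    coin). Each draw uses 2 uniforms from ``rand`` plus 1 more on a tie.

    Returns the boolean keep-mask.
    """
    n = mass.shape[0]
    alive = np.ones(n, dtype=np.bool_)
    idx = np.arange(n)
    m = n
    total = 0.0
    for i in range(n):
        total += mass[i]
    r = 0
    while total > capacity and m >= 2:
        i = int(rand[r] * m)
        r += 1
        j = int(rand[r] * (m - 1))
        r += 1
        if j >= i:
            j += 1
        a = idx[i]
        b = idx[j]
        if ap[a] > ap[b]:
            loser_pos = j
            loser = b
        elif ap[b] > ap[a]:
            loser_pos = i
            loser = a
        else:
            if rand[r] < 0.5:
                loser_pos = i
                loser = a
            else:
                loser_pos = j
                loser = b
            r += 1
        total -= mass[loser]
        alive[loser] = False
        m -= 1
        idx[loser_pos] = idx[m]
    return alive


def _meiosis_express_loop(pool, refs_m, refs_f, picks_m, picks_f, child, phen,
                          tol_min, shape_min, adult_min, adult_max):
    """Gather gametes and express offspring phenotypes in one fused pass.

    Valid for the one-gene-per-trait architecture (gene g codes trait g, so
    the expressed trait is the mean of the two inherited alleles, clamped to
    the legal domain). Trait slots: 1/3 tolerances, 4 seed mass, 5 adult
    mass, 6 dispersal scale, 7 dispersal shape.
    """
    n, _, g_total = child.shape
    for i in range(n):
        rm = refs_m[i]
        rf = refs_f[i]
        for g in range(g_total):
            c0 = pool[rm, picks_m[i, g], g]
            c1 = pool[rf, picks_f[i, g], g]
            child[i, 0, g] = c0
            child[i, 1, g] = c1
            phen[i, g] = 0.5 * (c0 + c1)
        if phen[i, 1] < tol_min:
            phen[i, 1] = tol_min
        if phen[i, 3] < tol_min:
            phen[i, 3] = tol_min
        if phen[i, 5] < adult_min:
            phen[i, 5] = adult_min
        elif phen[i, 5] > adult_max:
            phen[i, 5] = adult_max
        hi = phen[i, 5] * (1.0 - 1e-9)
        if phen[i, 4] < tol_min:
            phen[i, 4] = tol_min
        elif phen[i, 4] > hi:
            phen[i, 4] = hi
        if phen[i, 6] < tol_min:
            phen[i, 6] = tol_min
        if phen[i, 7] < shape_min:
            phen[i, 7] = shape_min


def _dispersal_fate_loop(phen, src_r, src_c, u_dist, u_ang, temps, precs, side,
                         out_row, out_col, out_at, out_ap, on_island):
    """Kernel-sample displacement, locate the landing cell, and evaluate the
    two Gaussian niche terms against it, one fused pass over the seed rain."""
    n = phen.shape[0]
    two_pi = 6.283185307179586
    for i in range(n):
        u = u_dist[i]
        if u <= 0.0:
            d = 0.0
        else:
            d = phen[i, 6] * np.exp(np.log(u / (1.0 - u)) / phen[i, 7])
        ang = two_pi * u_ang[i]
        x = src_c[i] + d * np.cos(ang)
        y = src_r[i] + d * np.sin(ang)
        col = int(np.floor(x + 0.5))
        row = int(np.floor(y + 0.5))
        if row < 0 or row >= side or col < 0 or col >= side:
            on_island[i] = False
            out_at[i] = 0.0
            out_ap[i] = 0.0
            continue
        on_island[i] = True
        out_row[i] = row
        out_col[i] = col
        dt = (temps[row, col] - phen[i, 0]) / phen[i, 1]
        dp = (precs[row, col] - phen[i, 2]) / phen[i, 3]
        out_at[i] = np.exp(-0.5 * dt * dt)
        out_ap[i] = np.exp(-0.5 * dp * dp)


try:  # numba is an optional accelerator; the fallbacks are the same functions
    from numba import njit

    compete_loop = njit(cache=True)(_compete_loop)
    meiosis_express_loop = njit(cache=True, fastmath=True)(_meiosis_express_loop)
    dispersal_fate_loop = njit(cache=True, fastmath=True)(_dispersal_fate_loop)
except ImportError:  # pragma: no cover
    compete_loop = _compete_loop
    meiosis_express_loop = _meiosis_express_loop
    dispersal_fate_loop = _dispersal_fate_loop


def max_removals(mass: np.ndarray, capacity: float) -> int:
    """Upper bound on competition removals (every removal frees >= min mass)."""
    total = float(mass.sum())
    if total <= capacity:
        return 0
    smallest = float(mass.min())
    if smallest <= 0:
        return mass.shape[0] - 1
    k = int(np.ceil((total - capacity) / smallest))
    return min(k, mass.shape[0] - 1)
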