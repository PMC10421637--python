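"""Numba kernels for the Monte Carlo samplers.

Kept separate so the samplers stay readable; every kernel is deterministic
given its seed (numba maintains its own Mersenne-Twister state in nopython
mode, seeded inside the kernel).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_ising(J, h, beta, n_burn, K, thin, seed, relabel):
    """Random-scan heat-bath sampling of an Ising model (+-1 spins).

    One sweep = n single-site updates at uniformly random sites. Records K
    configurations, one every `thin` sweeps after `n_burn` sweeps of burn-in.
    When `relabel` is true a global spin flip is applied with probability 1/2
    after each recorded configuration (valid only for zero field).
    """
    np.random.seed(seed)
    n = J.shape[0]
    s = np.empty(n, dtype=np.float64)
    for i in range(n):
        s[i] = 1.0 if np.random.random() < 0.5 else -1.0
    out = np.empty((K, n), dtype=np.int8)

    total_sweeps = n_burn + K * thin
    k = 0
    for sweep in range(total_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            f = h[i]
            for j in range(n):
                f += J[i, j] * s[j]
            p = 1.0 / (1.0 + np.exp(-2.0 * beta * f))
            s[i] = 1.0 if np.random.random() < p else -1.0
        if sweep >= n_burn and (sweep - n_burn + 1) % thin == 0:
            for i in range(n):
                out[k, i] = np.int8(s[i])
            k += 1
            if relabel and np.random.random() < 0.5:
                for i in range(n):
                    s[i] = -s[i]
    return out


@njit(cache=False)
def gibbs_potts(J, q, beta, n_burn, K, thin, seed, relabel):
    """Random-scan heat-bath sampling of a q-state Potts model (states 0..q-1).

    Kronecker-delta interactions; after each recorded configuration a uniform
    random permutation of the q labels is applied to the chain (zero-field
    symmetry), restoring ergodicity across symmetry-broken modes.
    """
    np.random.seed(seed)
    n = J.shape[0]
    s = np.empty(n, dtype=np.int64)
    for i in range(n):
        s[i] = np.random.randint(0, q)
    out = np.empty((K, n), dtype=np.int8)
    weights = np.empty(q, dtype=np.float64)
    perm = np.empty(q, dtype=np.int64)

    total_sweeps = n_burn + K * thin
    k = 0
    for sweep in range(total_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            for a in range(q):
                weights[a] = 0.0
            for j in range(n):
                if J[i, j] != 0.0:
                    weights[s[j]] += J[i, j]
            total = 0.0
            for a in range(q):
                weights[a] = np.exp(beta * weights[a])
                total += weights[a]
            u = np.random.random() * total
            acc = 0.0
            chosen = q - 1
            for a in range(q):
                acc += weights[a]
                if u < acc:
                    chosen = a
                    break
            s[i] = chosen
        if sweep >= n_burn and (sweep - n_burn + 1) % thin == 0:
            for i in range(n):
                out[k, i] = np.int8(s[i])
            k += 1
            if relabel:
                for a in range(q):  # Fisher-Yates
                    perm[a] = a
                for a in range(q - 1, 0, -1):
                    b = np.random.randint(0, a + 1)
                    tmp = perm[a]
                    perm[a] = perm[b]
                    perm[b] = tmp
                for i in range(n):
                    s[i] = perm[s[i]]
    return out


@njit(cache=False)
def _mix32(seed, k, e):
    """SplitMix-style mixer: a well-spread 32-bit chunk seed from (seed, k, e)."""
    z = seed * np.int64(0x9E3779B97F4A7C15) + k * np.int64(0xBF58476D1CE4E5B9) + e + 1
    z = (z ^ (z >> 30)) * np.int64(0x94D049BB133111EB)
    z = z ^ (z >> 31)
    return z & np.int64(0xFFFFFFFF)


@njit(cache=False)
def cftp_ising_batch(J, h, beta, K, seed, max_epoch):
    """K independent exact draws by monotone coupling from the past.

    The randomness for chunk e of sample k (the sweeps in (-2^e, -2^(e-1)]
    times the past) is a pure function of (seed, k, e), so restarting from
    further back reuses it verbatim, as exactness requires. Returns the
    sample matrix, a sandwich-order flag, and the index of the first sample
    that failed to coalesce within 2^max_epoch sweeps (-1 if none).
    """
    n = J.shape[0]
    out = np.empty((K, n), dtype=np.int8)
    upper = np.empty(n, dtype=np.float64)
    lower = np.empty(n, dtype=np.float64)
    sandwich_ok = True
    for k in range(K):
        epoch = 0
        done = False
        while not done:
            for i in range(n):
                upper[i] = 1.0
                lower[i] = -1.0
            for e in range(epoch, -1, -1):  # oldest chunk first
                sweeps = 1 if e == 0 else 2 ** (e - 1)
                np.random.seed(_mix32(np.int64(seed), np.int64(k), np.int64(e)))
                for _t in range(sweeps * n):
                    i = np.random.randint(0, n)
                    u = np.random.random()
                    fu = h[i]
                    fl = h[i]
                    for j in range(n):
                        fu += J[i, j] * upper[j]
                        fl += J[i, j] * lower[j]
                    pu = 1.0 / (1.0 + np.exp(-2.0 * beta * fu))
                    pl = 1.0 / (1.0 + np.exp(-2.0 * beta * fl))
                    upper[i] = 1.0 if u < pu else -1.0
                    lower[i] = 1.0 if u < pl else -1.0
                    if lower[i] > upper[i]:
                        sandwich_ok = False
            done = True
            for i in range(n):
                if upper[i] != lower[i]:
                    done = False
                    break
            if done:
                for i in range(n):
                    out[k, i] = np.int8(upper[i])
            else:
                epoch += 1
                if epoch > max_epoch:
                    return out, sandwich_ok, k
    return out, sandwich_ok, -1


@njit(cache=False)
def cftp_pass(J, h, beta, sites, unifs, upper, lower):
    """Evolve the two bounding chains through one block of randomness.

    Heat-bath updates driven by shared (site, uniform) streams preserve the
    componentwise order lower <= upper for ferromagnetic couplings. Returns
    False if the sandwich property was ever violated (should not happen).
    """
    n = J.shape[0]
    ok = True
    for t in range(sites.shape[0]):
        i = sites[t]
        u = unifs[t]
        fu = h[i]
        fl = h[i]
        for j in range(n):
            fu += J[i, j] * upper[j]
            fl += J[i, j] * lower[j]
        pu = 1.0 / (1.0 + np.exp(-2.0 * beta * fu))
        pl = 1.0 / (1.0 + np.exp(-2.0 * beta * fl))
        upper[i] = 1.0 if u < pu else -1.0
        lower[i] = 1.0 if u < pl else -1.0
        if lower[i] > upper[i]:
            ok = False
    return ok
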