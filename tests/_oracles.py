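"""Independent oracles used by the test suite.

Each routine recomputes a quantity by a route deliberately different from
the implementation it checks: explicit per-step loops for the shear
indices, a finite-difference radial solver (no Bessel functions) for the
pulsatile tube wall shear, and exhaustive sign-assignment enumeration for
the Wilcoxon signed-rank null.
"""

from itertools import product

import numpy as np


def tawss_loop(wss: np.ndarray) -> np.ndarray:
    """Brute-force per-face TAWSS: explicit loop over faces and steps."""
    n_faces, n_steps, _ = wss.shape
    out = np.zeros(n_faces)
    for f in range(n_faces):
        acc = 0.0
        for t in range(n_steps):
            x, y, z = wss[f, t]
            acc += (x * x + y * y + z * z) ** 0.5
        out[f] = acc / n_steps
    return out


def osi_loop(wss: np.ndarray) -> np.ndarray:
    """Brute-force per-face OSI with explicit component sums."""
    n_faces, n_steps, _ = wss.shape
    out = np.zeros(n_faces)
    for f in range(n_faces):
        sx = sy = sz = smag = 0.0
        for t in range(n_steps):
            x, y, z = wss[f, t]
            sx += x
            sy += y
            sz += z
            smag += (x * x + y * y + z * z) ** 0.5
        if smag > 0:
            out[f] = 0.5 * (1.0 - (sx * sx + sy * sy + sz * sz) ** 0.5 / smag)
    return out


def weighted_mean_loop(values, areas) -> float:
    num = den = 0.0
    for v, a in zip(values, areas):
        num += v * a
        den += a
    return num / den


def fd_wall_shear(harmonics, radius_mm: float, model, n_steps: int,
                  nr: int = 600) -> np.ndarray:
    """Finite-difference radial solver for pulsatile tube wall shear.

    For each flow harmonic the axisymmetric momentum equation is
    discretised in the radius (second-order central differences, symmetry
    at the centreline, no-slip at the wall) and solved in the frequency
    domain as a bordered linear system whose extra unknown is the pressure
    gradient enforcing the prescribed flow rate.  No Bessel functions are
    involved anywhere.
    """
    mu, rho = model.mu_inf_pas, model.density_kg_m3
    nu = mu / rho
    R = radius_mm / 1000.0
    h = R / nr
    r = h * np.arange(nr + 1)
    c = harmonics.amplitudes_mls * 1e-6
    omega = harmonics.omega_rad_s

    w = np.ones(nr + 1)
    w[0] = w[-1] = 0.5
    w = 2.0 * np.pi * h * w * r

    tau_k = np.zeros(len(c), dtype=complex)
    for k in range(len(c)):
        iw = 1j * k * omega
        n_unk = nr
        A = np.zeros((n_unk + 1, n_unk + 1), dtype=complex)
        rhs = np.zeros(n_unk + 1, dtype=complex)
        for i in range(n_unk):
            if i == 0:
                A[0, 0] = iw + nu * 4.0 / h**2
                A[0, 1] = -nu * 4.0 / h**2
            else:
                A[i, i - 1] = -nu * (1.0 / h**2 - 1.0 / (2.0 * r[i] * h))
                A[i, i] = iw + nu * 2.0 / h**2
                if i + 1 < n_unk:
                    A[i, i + 1] = -nu * (1.0 / h**2 + 1.0 / (2.0 * r[i] * h))
            A[i, n_unk] = -1.0 / rho
        A[n_unk, :n_unk] = w[:n_unk]
        rhs[n_unk] = c[k]
        sol = np.linalg.solve(A, rhs)
        u = np.concatenate([sol[:n_unk], [0.0]])
        dudr_wall = (-4.0 * u[nr - 1] + u[nr - 2]) / (2.0 * h)
        tau_k[k] = -mu * dudr_wall

    t = (harmonics.period_s / n_steps) * np.arange(n_steps)
    kk = np.arange(len(tau_k))
    return (np.exp(1j * omega * np.outer(t, kk)) * tau_k).real.sum(axis=1)


def wilcoxon_exact_enumeration(diff: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = len(diff)
    ranks = rankdata(np.abs(diff))  # midranks for ties
    w_obs = ranks[diff > 0].sum()
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(rk for s, rk in zip(signs, ranks) if s)
        if min(w, total - w) <= stat_obs + 1e-12:
            count += 1
    return count / 2**n
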