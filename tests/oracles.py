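"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written with literal scalar loops and
textbook formulas, sharing no code with the package, so agreement is a
genuine cross-check rather than a tautology.
"""

import math

import numpy as np


def glcm_brute(window, offset, levels):
    """Double-loop symmetric co-occurrence tally -> (P, ordered pair count)."""
    P = np.zeros((levels, levels))
    X, Y, Z = window.shape
    npairs = 0
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                xx, yy, zz = x + offset[0], y + offset[1], z + offset[2]
                if 0 <= xx < X and 0 <= yy < Y and 0 <= zz < Z:
                    a, b = window[x, y, z] - 1, window[xx, yy, zz] - 1
                    P[a, b] += 1
                    P[b, a] += 1
                    npairs += 2
    return P / P.sum(), npairs


def haralick_brute(P):
    """The ten statistics from their literal definitions, scalar loops."""
    G = P.shape[0]
    lv = range(1, G + 1)
    px = {i: sum(P[i - 1][j - 1] for j in lv) for i in lv}
    mu = sum(i * px[i] for i in lv)
    var_marg = sum((i - mu) ** 2 * px[i] for i in lv)
    p_sum = {n: 0.0 for n in range(2, 2 * G + 1)}
    p_diff = {n: 0.0 for n in range(0, G)}
    for i in lv:
        for j in lv:
            p_sum[i + j] += P[i - 1][j - 1]
            p_diff[abs(i - j)] += P[i - 1][j - 1]
    asm = sum(P[i - 1][j - 1] ** 2 for i in lv for j in lv)
    if var_marg > 1e-12:
        corr = (sum(i * j * P[i - 1][j - 1] for i in lv for j in lv) - mu * mu) / var_marg
    else:
        corr = 0.0
    contrast = sum(n * n * p for n, p in p_diff.items())
    idm = sum(P[i - 1][j - 1] / (1 + (i - j) ** 2) for i in lv for j in lv)
    variance = sum((i - mu) ** 2 * P[i - 1][j - 1] for i in lv for j in lv)
    sa = sum(n * p for n, p in p_sum.items())
    sv = sum((n - sa) ** 2 * p for n, p in p_sum.items())
    se = -sum(p * math.log2(p) for p in p_sum.values() if p > 0)
    ent = -sum(
        P[i - 1][j - 1] * math.log2(P[i - 1][j - 1])
        for i in lv
        for j in lv
        if P[i - 1][j - 1] > 0
    )
    da = sum(n * p for n, p in p_diff.items())
    dv = sum((n - da) ** 2 * p for n, p in p_diff.items())
    return np.array([asm, corr, contrast, idm, variance, sa, sv, se, ent, dv])


def random_symmetric_glcm(rng, levels):
    M = rng.random((levels, levels))
    P = M + M.T
    return P / P.sum()


def ellipsoid_count(shape, center, radii):
    """Scalar-loop membership count of a discrete ellipsoid."""
    cnt = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if (
                    ((x - center[0]) / radii[0]) ** 2
                    + ((y - center[1]) / radii[1]) ** 2
                    + ((z - center[2]) / radii[2]) ** 2
                    <= 1
                ):
                    cnt += 1
    return cnt


def enhancement_quadrature(t, A, kep, kel, tau):
    """Enhancement via numerical quadrature of the infusion convolution."""
    from scipy.integrate import quad

    t_min, tau_min = t / 60.0, tau / 60.0
    if t_min == 0:
        return 0.0
    u = min(t_min, tau_min)

    def integrand(s):
        return math.exp(-kel * (t_min - s)) - math.exp(-kep * (t_min - s))

    val, _ = quad(integrand, 0, u, epsabs=1e-13, epsrel=1e-13)
    return (A / tau_min) * kep * val / (kep - kel)
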