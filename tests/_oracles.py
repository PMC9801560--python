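"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force: dense multi-dimensional
quadrature for 2-3 base-pair chains, exhaustive k-mer enumeration for string
kernels, a generic constrained-QP solve for the SVM dual, and the pairwise
Mann-Whitney statistic for ROC areas.  None of it shares code with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize

from pbdtss.pbd import onsite_potential, stacking_potential


# -- dense quadrature for N <= 3 --------------------------------------------

def dense_boltzmann_factors(seq, temperature, grid, params):
    """Per-position weighted on-site factors and adjacent coupling matrices."""
    y, w = grid.nodes, grid.weights
    beta = 1.0 / (params.kB * temperature)
    vs = []
    for b in seq:
        pair = "AT" if b in "AT" else "GC"
        vs.append(w * np.exp(-beta * onsite_potential(y, pair, params)))
    mats = []
    for i in range(1, len(seq)):
        dimer = seq[i - 1] + seq[i]
        mats.append(np.exp(-beta * stacking_potential(y[None, :], y[:, None], dimer, params)))
    return vs, mats


def dense_weight(seq, temperature, grid, params, masks=None):
    """Brute-force configuration integral with optional per-position masks.

    ``masks[i]`` is a boolean/float node mask or None (unconstrained).
    Returns the raw statistical weight (not its log); N must be 2 or 3.
    """
    vs, mats = dense_boltzmann_factors(seq, temperature, grid, params)
    if masks is not None:
        vs = [v if m is None else v * m for v, m in zip(vs, masks)]
    if len(seq) == 2:
        return float(np.einsum("i,j,ji->", vs[0], vs[1], mats[0]))
    if len(seq) == 3:
        return float(np.einsum("i,j,k,ji,kj->", vs[0], vs[1], vs[2], mats[0], mats[1]))
    raise ValueError("dense oracle only supports chains of 2 or 3 base pairs")


def dense_dsdna_denominator(seq, temperature, grid, params):
    """Z_I - Z_II over the grid domain, by dense quadrature."""
    om = grid.open_mask
    zi = dense_weight(seq, temperature, grid, params)
    zii = dense_weight(seq, temperature, grid, params, masks=[om] * len(seq))
    return zi - zii


def dense_exact_bubble(seq, temperature, grid, params, start, size):
    """P_bub for the open run [start, start+size-1] (0-based), flanks closed."""
    n = len(seq)
    om, cm = grid.open_mask, grid.closed_mask
    masks = []
    for i in range(n):
        if start <= i < start + size:
            masks.append(om)
        elif i in (start - 1, start + size):
            masks.append(cm)
        else:
            masks.append(None)
    if size == n:
        return 0.0  # the all-open state is excluded from the dsDNA ensemble
    num = dense_weight(seq, temperature, grid, params, masks=masks)
    return num / dense_dsdna_denominator(seq, temperature, grid, params)


def dense_opening(seq, temperature, grid, params, j):
    """<theta_j>_mu = (Z(j open) - Z_II) / (Z_I - Z_II) by dense quadrature."""
    om = grid.open_mask
    masks = [None] * len(seq)
    masks[j] = om
    zo = dense_weight(seq, temperature, grid, params, masks=masks)
    zii = dense_weight(seq, temperature, grid, params, masks=[om] * len(seq))
    return (zo - zii) / dense_dsdna_denominator(seq, temperature, grid, params)


# -- string kernels ----------------------------------------------------------

def naive_wd(s1, s2, d):
    """Direct double loop over k-mer orders and anchor positions."""
    L = len(s1)
    total = 0.0
    for k in range(1, d + 1):
        beta = 2.0 * (d - k + 1) / (d * (d + 1))
        for l in range(L - k + 1):
            if s1[l:l + k] == s2[l:l + k]:
                total += beta
    return total


def naive_wds(s1, s2, d, shift_max):
    """Direct triple loop for the shifted weighted-degree kernel."""
    L = len(s1)
    total = 0.0
    for k in range(1, d + 1):
        beta = 2.0 * (d - k + 1) / (d * (d + 1))
        for l in range(L - k + 1):
            for s in range(0, shift_max + 1):
                if l + s + k > L:
                    break
                w = 1.0 / (2.0 * (s + 1))
                total += beta * w * ((s1[l + s:l + s + k] == s2[l:l + k])
                                     + (s1[l:l + k] == s2[l + s:l + s + k]))
    return total


# -- SVM dual ----------------------------------------------------------------

def qp_dual_solve(K, y, C):
    """Generic solve of the soft-margin SVM dual with SLSQP.

    max sum(a) - 1/2 a^T (yy^T * K) a  s.t.  0 <= a <= C, sum a_i y_i = 0.
    Returns (alpha, objective value).
    """
    K = np.asarray(K, float)
    y = np.asarray(y, float)
    n = y.size
    Q = np.outer(y, y) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(neg_obj, x0=np.full(n, min(C, 1.0) / 2), jac=neg_grad,
                   bounds=[(0.0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   method="SLSQP", options={"maxiter": 2000, "ftol": 1e-12})
    if not res.success:
        raise RuntimeError(f"QP oracle failed: {res.message}")
    return res.x, -res.fun


def qp_decision_values(K_cross, K_train, y, alpha, C):
    """Decision values from an oracle dual solution (bias from margin SVs)."""
    y = np.asarray(y, float)
    alpha = np.asarray(alpha, float)
    margin = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    f_no_bias = K_train @ (alpha * y)
    bias = float(np.mean(y[margin] - f_no_bias[margin]))
    return np.asarray(K_cross, float) @ (alpha * y) + bias


# -- ROC ---------------------------------------------------------------------

def mann_whitney_auc(scores, labels):
    """Fraction of (positive, negative) pairs ranked correctly, ties half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    pos = s[y > 0]
    neg = s[y <= 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (pos.size * neg.size)
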