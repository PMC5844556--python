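"""Numerical kernels for the two-ligand transfer-matrix equilibrium.

The grand-canonical partition function of two competing ligands with hard
footprints on a 1-D lattice satisfies a short-memory linear recursion; to
avoid overflow the recursion is carried in log space via per-step ratios.
All heavy loops are numba-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "linear_start_probs",
    "circular_coverage",
    "linear_coverage",
]


@njit(cache=True)
def _forward_log(wy, wn, my, mn):
    """Cumulative log partition function lf[i] = log Z(sites 0..i-1).

    wy[j] / wn[j] are the statistical weights (K * c_free) of a YOYO /
    netropsin molecule starting at 0-based site j; weights of start
    positions that do not fit on the lattice must already be zero.
    """
    L = wy.shape[0]
    lf = np.zeros(L + 1)
    for i in range(1, L + 1):
        r = 1.0
        if i >= my and wy[i - my] > 0.0:
            r += wy[i - my] * np.exp(lf[i - my] - lf[i - 1])
        if i >= mn and wn[i - mn] > 0.0:
            r += wn[i - mn] * np.exp(lf[i - mn] - lf[i - 1])
        lf[i] = lf[i - 1] + np.log(r)
    return lf


@njit(cache=True)
def _backward_log(wy, wn, my, mn):
    """Cumulative log partition function lb[i] = log Z(sites i..L-1)."""
    L = wy.shape[0]
    lb = np.zeros(L + 1)
    for i in range(L - 1, -1, -1):
        r = 1.0
        if i + my <= L and wy[i] > 0.0:
            r += wy[i] * np.exp(lb[i + my] - lb[i + 1])
        if i + mn <= L and wn[i] > 0.0:
            r += wn[i] * np.exp(lb[i + mn] - lb[i + 1])
        lb[i] = lb[i + 1] + np.log(r)
    return lb


@njit(cache=True)
def linear_start_probs(wy, wn, my, mn):
    """Per-site probabilities that a ligand *starts* at each site (linear).

    Returns (py_start, pn_start, logZ). Start probabilities are exact
    equilibrium marginals: P_start_s(j) = w_s(j) Z(0..j-1) Z(j+m_s..) / Z.
    """
    L = wy.shape[0]
    lf = _forward_log(wy, wn, my, mn)
    lb = _backward_log(wy, wn, my, mn)
    logZ = lf[L]
    py = np.zeros(L)
    pn = np.zeros(L)
    for j in range(L):
        if j + my <= L and wy[j] > 0.0:
            py[j] = wy[j] * np.exp(lf[j] + lb[j + my] - logZ)
        if j + mn <= L and wn[j] > 0.0:
            pn[j] = wn[j] * np.exp(lf[j] + lb[j + mn] - logZ)
    return py, pn, logZ


@njit(cache=True)
def _coverage_from_starts(p_start, m):
    """Per-site probability of being covered, p_cov[i] = sum of starts in
    (i-m, i]."""
    L = p_start.shape[0]
    cov = np.zeros(L)
    run = 0.0
    for i in range(L):
        run += p_start[i]
        if i >= m:
            run -= p_start[i - m]
        cov[i] = run
    return cov


@njit(cache=True)
def linear_coverage(wy, wn, my, mn):
    """Coverage probabilities and expected ligand counts on a linear lattice.

    Returns (cov_y, cov_n, n_y, n_n) where n_s is the expected number of
    bound ligands of species s.
    """
    py, pn, _ = linear_start_probs(wy, wn, my, mn)
    cov_y = _coverage_from_starts(py, my)
    cov_n = _coverage_from_starts(pn, mn)
    return cov_y, cov_n, py.sum(), pn.sum()


@njit(cache=True)
def circular_coverage(wy_c, wn_c, my, mn):
    """Coverage probabilities and expected counts on a circular lattice.

    wy_c / wn_c are the circular weights (every start position valid,
    footprints wrap). Solved exactly by conditioning on the bond between
    site L-1 and site 0: either no ligand crosses it (one linear problem)
    or a specific ligand straddles it (one linear problem per wrapped
    start position).
    """
    L = wy_c.shape[0]
    n_cases = 1 + (my - 1) + (mn - 1)
    log_w = np.full(n_cases, -np.inf)
    cov_y_cases = np.zeros((n_cases, L))
    cov_n_cases = np.zeros((n_cases, L))
    ny_cases = np.zeros(n_cases)
    nn_cases = np.zeros(n_cases)

    # case 0: bond not crossed -> plain linear lattice
    wy0 = wy_c.copy()
    wn0 = wn_c.copy()
    for j in range(L - my + 1, L):
        if j >= 0:
            wy0[j] = 0.0
    for j in range(L - mn + 1, L):
        if j >= 0:
            wn0[j] = 0.0
    py, pnn, logZ0 = linear_start_probs(wy0, wn0, my, mn)
    log_w[0] = logZ0
    cov_y_cases[0] = _coverage_from_starts(py, my)
    cov_n_cases[0] = _coverage_from_starts(pnn, mn)
    ny_cases[0] = py.sum()
    nn_cases[0] = pnn.sum()

    # crossing cases: ligand of species s starts at j in {L-m+1..L-1}
    case = 1
    for s in range(2):
        m = my if s == 0 else mn
        w_s = wy_c if s == 0 else wn_c
        for j in range(L - m + 1, L):
            if j < 0:
                continue
            if w_s[j] <= 0.0:
                case += 1
                continue
            # ligand covers sites j..L-1 and 0..(j+m-L-1);
            # free stretch = sites (j+m-L)..(j-1), length L-m
            tail = j + m - L  # first free site
            free_len = L - m
            sub_wy = np.zeros(free_len)
            sub_wn = np.zeros(free_len)
            for t in range(free_len):
                src = tail + t
                sub_wy[t] = wy_c[src]
                sub_wn[t] = wn_c[src]
            # zero starts that would not fit inside the free stretch
            for t in range(max(0, free_len - my + 1), free_len):
                sub_wy[t] = 0.0
            for t in range(max(0, free_len - mn + 1), free_len):
                sub_wn[t] = 0.0
            spy, spn, sublogZ = linear_start_probs(sub_wy, sub_wn, my, mn)
            scov_y = _coverage_from_starts(spy, my)
            scov_n = _coverage_from_starts(spn, mn)
            log_w[case] = np.log(w_s[j]) + sublogZ
            for t in range(free_len):
                src = tail + t
                cov_y_cases[case, src] = scov_y[t]
                cov_n_cases[case, src] = scov_n[t]
            # fixed crossing ligand covers its own sites with probability 1
            for k in range(m):
                src = (j + k) % L
                if s == 0:
                    cov_y_cases[case, src] = 1.0
                else:
                    cov_n_cases[case, src] = 1.0
            ny_cases[case] = spy.sum() + (1.0 if s == 0 else 0.0)
            nn_cases[case] = spn.sum() + (1.0 if s == 1 else 0.0)
            case += 1

    lmax = np.max(log_w)
    probs = np.exp(log_w - lmax)
    probs /= probs.sum()
    cov_y = np.zeros(L)
    cov_n = np.zeros(L)
    n_y = 0.0
    n_n = 0.0
    for c in range(n_cases):
        if probs[c] > 0.0:
            cov_y += probs[c] * cov_y_cases[c]
            cov_n += probs[c] * cov_n_cases[c]
            n_y += probs[c] * ny_cases[c]
            n_n += probs[c] * nn_cases[c]
    return cov_y, cov_n, n_y, n_n
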