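"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: the lattice
oracle enumerates every legal ligand configuration explicitly, and the
per-window Pearson oracle recomputes each correlation from scratch.
"""

import numpy as np


def enumerate_lattice_coverage(wy, wn, my, mn, circular):
    """Exact per-site ligand coverage probabilities by exhaustive
    enumeration of all legal configurations (feasible for L <= ~20).

    Weights are per start site; on a linear lattice, start positions whose
    footprint does not fit contribute nothing.
    """
    L = len(wy)
    cov_y = np.zeros(L)
    cov_n = np.zeros(L)
    Z = 0.0

    def cells_for(pos, m):
        if circular:
            return [(pos + k) % L for k in range(m)]
        if pos + m > L:
            return None
        return list(range(pos, pos + m))

    def dfs(pos, mask, weight, y_cells, n_cells):
        nonlocal Z, cov_y, cov_n
        if pos == L:
            Z += weight
            for c in y_cells:
                cov_y[c] += weight
            for c in n_cells:
                cov_n[c] += weight
            return
        dfs(pos + 1, mask, weight, y_cells, n_cells)
        for w, m, bucket in ((wy[pos], my, "y"), (wn[pos], mn, "n")):
            if w <= 0:
                continue
            cells = cells_for(pos, m)
            if cells is None or any(mask >> c & 1 for c in cells):
                continue
            nm = mask
            for c in cells:
                nm |= 1 << c
            if bucket == "y":
                dfs(pos + 1, nm, weight * w, y_cells + cells, n_cells)
            else:
                dfs(pos + 1, nm, weight * w, y_cells, n_cells + cells)

    dfs(0, 0, 1.0, [], [])
    return cov_y / Z, cov_n / Z


def naive_window_pearson(contig, reference):
    """Per-window Pearson correlations against a circular reference,
    forward block then reversed-contig block, computed one window at a
    time with np.corrcoef."""
    c = np.asarray(contig, float)
    r = np.asarray(reference, float)
    m, x_max = len(c), len(r)
    ext = np.concatenate([r, r])
    out = np.empty(2 * x_max)
    for x in range(x_max):
        w = ext[x : x + m]
        out[x] = np.corrcoef(c, w)[0, 1]
        out[x_max + x] = np.corrcoef(c[::-1], w)[0, 1]
    return out
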